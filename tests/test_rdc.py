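"""Dipolar constants, RDC prediction, single-tensor SVD fitting and scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import constants

from statescope.ensemble_io import AtomSite, Ensemble, Frame
from statescope.rdc_analysis import (
    DegenerateFitError,
    RDCRecord,
    SaupeTensor,
    bond_unit_vectors,
    correlation_curve,
    dmax,
    flag_outliers,
    predict_rdc,
    read_rdc_table,
    splittings_to_rdc,
    svd_fit,
    write_rdc_table,
)
from statescope.synthetic_data import (
    DEFAULT_TRUE_TENSOR,
    RDCSimSpec,
    make_synthetic_rdcs,
    make_toy_domain,
)


class TestDmax:
    def test_inverse_cube_law(self):
        assert dmax("H-N", 2.082) == pytest.approx(dmax("H-N", 1.041) / 8.0)

    def test_gamma_product_ratio(self):
        r = 1.3
        gamma_h, gamma_n, gamma_c = 267.522187e6, -27.116e6, 67.2828e6
        expected = (gamma_h * gamma_n) / (gamma_n * gamma_c)
        assert dmax("H-N", r) / dmax("N-C'", r) == pytest.approx(expected)

    def test_hand_evaluated_constant_for_hn(self):
        """Recompute the static dipolar constant from tabulated constants."""
        r = 1.041e-10
        gamma_h, gamma_n = 267.522187e6, -27.116e6
        b = -(constants.mu_0 * constants.hbar * gamma_h * gamma_n
              / (4.0 * np.pi * r ** 3)) / (2.0 * np.pi)
        assert dmax("H-N") == pytest.approx(b, rel=1e-12)
        assert abs(dmax("H-N")) == pytest.approx(10.79e3, rel=0.01)

    def test_unknown_type_rejected(self):
        with pytest.raises(KeyError):
            dmax("HA-HB")


def _two_atom_frame(p1, p2, resnum=5):
    sites = [AtomSite("A", resnum, "ALA", "H", np.asarray(p1, float)),
             AtomSite("A", resnum, "ALA", "N", np.asarray(p2, float))]
    return Frame(sites, 0)


class TestBondVectors:
    def test_axis_aligned_pair(self):
        frame = _two_atom_frame([0, 0, 0], [0, 0, 1.04])
        u = bond_unit_vectors(frame, [RDCRecord(5, "H-N", 0.0)])
        np.testing.assert_allclose(u[0], [0, 0, 1], atol=1e-12)
        assert np.linalg.norm(u[0]) == pytest.approx(1.0, abs=1e-12)

    def test_translation_invariance(self):
        f1 = _two_atom_frame([0, 0, 0], [0.6, 0.8, 0.0])
        f2 = _two_atom_frame([10, -5, 3], [10.6, -4.2, 3.0])
        rec = [RDCRecord(5, "H-N", 0.0)]
        np.testing.assert_allclose(bond_unit_vectors(f1, rec),
                                   bond_unit_vectors(f2, rec), atol=1e-12)

    def test_constructed_amide_h_is_planar_symmetric(self, toy_frame):
        """Built N-H bisects C(i-1)-N-CA: both flanking angles agree to 1 deg."""
        rec = [RDCRecord(18, "H-N", 0.0)]
        u = bond_unit_vectors(toy_frame, rec)[0]
        n = toy_frame.atom("A", 18, "N").position
        ca = toy_frame.atom("A", 18, "CA").position
        c_prev = toy_frame.atom("A", 17, "C").position
        h = n + 1.041 * u

        def angle(p, q, r):
            a, b = p - q, r - q
            return np.degrees(np.arccos(a @ b / np.linalg.norm(a) / np.linalg.norm(b)))
        assert abs(angle(c_prev, n, h) - angle(ca, n, h)) < 1.0


class TestPredict:
    def test_axial_tensor_closed_form(self):
        s = 1e-3
        tensor = SaupeTensor([s, 0.0, 0.0, 0.0, 0.0])
        frame = _two_atom_frame([0, 0, 0], [0, 0, 1.041])
        d = predict_rdc(frame, tensor, [RDCRecord(5, "H-N", 0.0)])
        assert d[0] == pytest.approx(dmax("H-N") * s, rel=1e-12)

    def test_magic_angle_vanishes(self):
        s = 1e-3
        tensor = SaupeTensor([s, 0.0, 0.0, 0.0, 0.0])
        theta = np.arccos(1.0 / np.sqrt(3.0))
        v = np.array([np.sin(theta), 0.0, np.cos(theta)]) * 1.041
        frame = _two_atom_frame([0, 0, 0], v)
        d = predict_rdc(frame, tensor, [RDCRecord(5, "H-N", 0.0)])
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_ensemble_prediction_is_frame_mean(self, toy_frame, rng):
        frames = [toy_frame.transformed(np.eye(3), np.zeros(3))]
        from scipy.spatial.transform import Rotation
        for k in range(3):
            R = Rotation.from_euler("xyz", rng.uniform(-90, 90, 3),
                                    degrees=True).as_matrix()
            frames.append(toy_frame.transformed(R, np.zeros(3)))
        for i, f in enumerate(frames):
            f.frame_index = i
        ens = Ensemble(frames)
        records = [RDCRecord(r, "H-N", 0.0) for r in range(10, 30)]
        ens_pred = predict_rdc(ens, DEFAULT_TRUE_TENSOR, records)
        per_frame = np.array([predict_rdc(f, DEFAULT_TRUE_TENSOR, records)
                              for f in frames])
        np.testing.assert_allclose(ens_pred, per_frame.mean(axis=0), atol=1e-12)


class TestSplittings:
    def _tables(self):
        iso = pd.DataFrame({"residue": [5, 6], "type": ["H-N", "H-N"],
                            "splitting_hz": [93.0, 94.0]})
        aniso = pd.DataFrame({"residue": [5, 6], "type": ["H-N", "H-N"],
                              "splitting_hz": [102.0, 94.0]})
        return iso, aniso

    def test_difference_convention(self):
        iso, aniso = self._tables()
        records = splittings_to_rdc(iso, aniso)
        assert records[0].value == pytest.approx(9.0)
        assert records[1].value == pytest.approx(0.0)

    def test_flip_sign_negates(self):
        iso, aniso = self._tables()
        plain = splittings_to_rdc(iso, aniso)
        flipped = splittings_to_rdc(iso, aniso, flip_sign=True)
        for a, b in zip(plain, flipped):
            assert b.value == pytest.approx(-a.value)

    def test_duplicate_keys_rejected(self):
        iso = pd.DataFrame({"residue": [5, 5], "type": ["H-N", "H-N"],
                            "splitting_hz": [93.0, 93.5]})
        with pytest.raises(ValueError):
            splittings_to_rdc(iso, iso)

    def test_unmatched_keys_dropped(self):
        iso, aniso = self._tables()
        aniso2 = pd.concat([aniso, pd.DataFrame(
            {"residue": [9], "type": ["H-N"], "splitting_hz": [80.0]})])
        records = splittings_to_rdc(iso, aniso2)
        assert {r.residue_number for r in records} == {5, 6}


class TestSVDFit:
    def test_noiseless_single_frame_recovery(self, toy_frame):
        """Synthetic RDCs from a known tensor refit exactly."""
        ens = Ensemble([toy_frame.copy()])
        records, truth = make_synthetic_rdcs(ens, RDCSimSpec(
            coupling_types=("H-N",)))
        records = records[:40]
        fit = svd_fit(ens, records)
        rel = np.abs(fit.tensor.independent_elements
                     - truth["tensor"].independent_elements) \
            / np.abs(truth["tensor"].independent_elements)
        assert rel.max() < 1e-8
        assert fit.pearson_r == pytest.approx(1.0, abs=1e-12)
        assert fit.q_factor == pytest.approx(0.0, abs=1e-10)

    def test_five_records_exact_interpolation(self, toy_frame):
        ens = Ensemble([toy_frame.copy()])
        records, _truth = make_synthetic_rdcs(ens, RDCSimSpec(
            coupling_types=("H-N",)))
        fit = svd_fit(ens, records[10:15])
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-9)

    def test_noisy_residual_scale_and_da_recovery(self, toy_frame):
        """sigma = 1 Hz noise on 200 records, single frame."""
        ens = Ensemble([toy_frame.transformed(np.eye(3), np.zeros(3))])
        big = make_toy_domain(101)
        ens = Ensemble([big])
        records, truth = make_synthetic_rdcs(ens, RDCSimSpec(
            noise_sd=1.0, coupling_types=("H-N", "C'-CA", "N-C'"), seed=42))
        records = records[:200]
        fit = svd_fit(ens, records)
        assert fit.rmsd == pytest.approx(1.0, rel=0.15)
        assert fit.tensor.magnitude == pytest.approx(
            truth["tensor"].magnitude, rel=0.05)

    def test_rank_deficient_geometry_rejected(self):
        sites = []
        for r in range(1, 9):
            sites.append(AtomSite("A", r, "ALA", "H", np.array([0.0, 0.0, r * 3.0])))
            sites.append(AtomSite("A", r, "ALA", "N",
                                  np.array([0.0, 0.0, r * 3.0 + 1.04])))
        frame = Frame(sites, 0)
        records = [RDCRecord(r, "H-N", 1.0) for r in range(1, 9)]
        with pytest.raises(DegenerateFitError):
            svd_fit(frame, records)

    def test_least_squares_optimality_monte_carlo(self, toy_frame, rng):
        """No random candidate tensor beats the SVD solution."""
        ens = Ensemble([toy_frame.copy()])
        records, _ = make_synthetic_rdcs(ens, RDCSimSpec(
            noise_sd=2.0, coupling_types=("H-N",), seed=8))
        fit = svd_fit(ens, records)
        obs = np.array([r.value for r in records])
        best_norm = np.linalg.norm(obs - fit.predicted)
        scale = np.abs(fit.tensor.independent_elements).max()
        for _ in range(1000):
            cand = SaupeTensor(fit.tensor.independent_elements
                               + rng.normal(0, scale, 5))
            pred = predict_rdc(ens, cand, records)
            assert np.linalg.norm(obs - pred) >= best_norm - 1e-12

    def test_linearity_in_observations(self, toy_frame):
        ens = Ensemble([toy_frame.copy()])
        records, _ = make_synthetic_rdcs(ens, RDCSimSpec(coupling_types=("H-N",)))
        fit1 = svd_fit(ens, records)
        doubled = [RDCRecord(r.residue_number, r.coupling_type, 2.0 * r.value)
                   for r in records]
        fit2 = svd_fit(ens, doubled)
        np.testing.assert_allclose(fit2.tensor.independent_elements,
                                   2.0 * fit1.tensor.independent_elements,
                                   rtol=1e-9)

    def test_parameter_recovery_over_replicates(self, endpoints):
        """Median Da error < 3%, rhombicity error < 10% at sigma = 0.5 Hz."""
        from statescope.synthetic_data import TwoStateSpec, make_two_state_ensemble
        alpha, beta, _lay = endpoints
        ens, _ = make_two_state_ensemble(TwoStateSpec(alpha, beta, n_frames=10,
                                                      seed=3))
        da_err, rh_err = [], []
        for rep in range(50):
            records, truth = make_synthetic_rdcs(ens, RDCSimSpec(
                noise_sd=0.5, coupling_types=("H-N", "C'-CA"), seed=500 + rep))
            fit = svd_fit(ens, records[:100], seed=rep)
            truth_t = truth["tensor"]
            da_err.append(abs(fit.tensor.magnitude - truth_t.magnitude)
                          / abs(truth_t.magnitude))
            rh_err.append(abs(fit.tensor.rhombicity - truth_t.rhombicity)
                          / abs(truth_t.rhombicity))
        assert np.median(da_err) < 0.03
        assert np.median(rh_err) < 0.10

    def test_subsampling_respects_max_structures(self, endpoints):
        from statescope.synthetic_data import TwoStateSpec, make_two_state_ensemble
        alpha, beta, _lay = endpoints
        ens, _ = make_two_state_ensemble(TwoStateSpec(alpha, beta, n_frames=12,
                                                      seed=6))
        records, _ = make_synthetic_rdcs(ens, RDCSimSpec(coupling_types=("H-N",)))
        fit = svd_fit(ens, records, max_structures=5, seed=1)
        assert fit.n_structures_used == 5


class TestCorrelationCurve:
    def test_full_size_is_deterministic(self, endpoints):
        from statescope.synthetic_data import TwoStateSpec, make_two_state_ensemble
        alpha, beta, _lay = endpoints
        ens, _ = make_two_state_ensemble(TwoStateSpec(alpha, beta, n_frames=8,
                                                      seed=4))
        records, _ = make_synthetic_rdcs(ens, RDCSimSpec(
            noise_sd=1.0, coupling_types=("H-N",), seed=9))
        r1 = correlation_curve(ens, records, [8], seed=1)
        r2 = correlation_curve(ens, records, [8], seed=2)
        assert r1[8] == r2[8]

    def test_self_consistent_noiseless_r_is_one(self, endpoints):
        from statescope.synthetic_data import TwoStateSpec, make_two_state_ensemble
        alpha, beta, _lay = endpoints
        ens, _ = make_two_state_ensemble(TwoStateSpec(alpha, beta, n_frames=6,
                                                      seed=10))
        records, _ = make_synthetic_rdcs(ens, RDCSimSpec(coupling_types=("H-N",)))
        curve = correlation_curve(ens, records, [6], seed=0)
        assert curve[6] == pytest.approx(1.0, abs=1e-10)

    def test_type_subset_matches_manual_pearson(self, toy_frame):
        ens = Ensemble([toy_frame.copy()])
        records, _ = make_synthetic_rdcs(ens, RDCSimSpec(
            noise_sd=1.5, coupling_types=("H-N", "C'-CA"), seed=12))
        curve = correlation_curve(ens, records, [1], seed=0, type_filter="H-N")
        fit = svd_fit(ens, records, seed=0)
        mask = np.array([r.coupling_type == "H-N" for r in records])
        obs = np.array([r.value for r in records])[mask]
        pred = fit.predicted[mask]
        manual = np.corrcoef(obs, pred)[0, 1]
        assert curve[1] == pytest.approx(manual, abs=1e-12)


class TestOutliers:
    def test_equal_residuals_none_flagged(self):
        result = _fake_result(np.full(10, 0.7))
        assert flag_outliers(result) == []

    def test_single_large_residual_flagged(self):
        resid = np.full(20, 0.1)
        resid[7] = 10.0 * np.std(np.delete(resid, 7)) + 5.0
        result = _fake_result(resid)
        assert flag_outliers(result) == [107]

    def test_matches_manual_computation_on_fixture(self):
        resid = np.array([0.2, -0.1, 0.4, -0.3, 0.1, 2.5, -0.2, 0.3, -0.4, 0.05])
        result = _fake_result(resid)
        sd = np.std(resid)
        expected = [100 + i for i, r in enumerate(resid) if abs(r) > 2.0 * sd]
        assert flag_outliers(result, 2.0) == expected


def _fake_result(residuals):
    from statescope.rdc_analysis import RDCFitResult
    records = [RDCRecord(100 + i, "H-N", float(v)) for i, v in enumerate(residuals)]
    return RDCFitResult(
        tensor=DEFAULT_TRUE_TENSOR, records=records,
        predicted=np.zeros(len(residuals)), residuals=np.asarray(residuals),
        pearson_r=0.0, q_factor=0.0, rmsd=0.0,
        outlier_flags=np.zeros(len(residuals), dtype=bool),
        n_structures_used=1)


class TestTables:
    def test_rdc_table_roundtrip(self, tmp_path, toy_frame):
        ens = Ensemble([toy_frame.copy()])
        records, _ = make_synthetic_rdcs(ens, RDCSimSpec(
            noise_sd=0.3, coupling_types=("H-N",), seed=2))
        path = tmp_path / "rdc.tsv"
        write_rdc_table(records, path)
        loaded = read_rdc_table(path)
        assert len(loaded) == len(records)
        for a, b in zip(records, loaded):
            assert a.residue_number == b.residue_number
            assert a.coupling_type == b.coupling_type
            assert b.value == pytest.approx(a.value, abs=1e-4)
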