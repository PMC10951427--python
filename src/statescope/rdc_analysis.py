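"""Residual dipolar coupling prediction and single-tensor ensemble fitting.

An RDC reports the orientation of an internuclear vector relative to the
molecular alignment frame:

    D = Dmax(type) * u^T S u

with ``u`` the unit bond vector and ``S`` the symmetric traceless Saupe
order matrix (5 independent elements).  Fitting ``S`` to measured RDCs is
a linear least-squares problem solved by singular value decomposition.
For an ensemble, all frames share one tensor: the design-matrix rows are
averaged over frames, so the fit yields a single alignment tensor and an
ensemble-averaged set of back-calculated couplings.

Goodness of fit is summarised by the Pearson correlation, the RMSD of the
residuals, and the Q factor rms(residual)/rms(observed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import constants

from .ensemble_io import Ensemble, Frame, MissingAtomError

logger = logging.getLogger("statescope")

__all__ = [
    "SaupeTensor",
    "RDCRecord",
    "RDCFitResult",
    "DegenerateFitError",
    "COUPLING_TYPES",
    "EFFECTIVE_BOND_LENGTHS",
    "dmax",
    "splittings_to_rdc",
    "bond_unit_vectors",
    "predict_rdc",
    "svd_fit",
    "correlation_curve",
    "flag_outliers",
    "read_rdc_table",
    "write_rdc_table",
]


class DegenerateFitError(ValueError):
    """Design matrix rank-deficient (e.g. all bond vectors parallel)."""


# Gyromagnetic ratios, rad s^-1 T^-1.
_GAMMA = {"H": 267.522187e6, "N": -27.116e6, "C": 67.2828e6}

#: (atom_i, residue offset_i, atom_j, offset_j, gamma_i, gamma_j) per type.
#: N-C' and H-C' span residue i and the preceding carbonyl C'(i-1).
COUPLING_TYPES = {
    "H-N": (("H", 0), ("N", 0), "H", "N"),
    "N-C'": (("N", 0), ("C", -1), "N", "C"),
    "H-C'": (("H", 0), ("C", -1), "H", "C"),
    "C'-CA": (("C", 0), ("CA", 0), "C", "C"),
    "CA-HA": (("CA", 0), ("HA", 0), "C", "H"),
}

#: Effective internuclear distances (A), solution-NMR convention.
EFFECTIVE_BOND_LENGTHS = {
    "H-N": 1.041,
    "N-C'": 1.329,
    "H-C'": 2.085,
    "C'-CA": 1.526,
    "CA-HA": 1.117,
}


def dmax(coupling_type: str, effective_bond_length: float | None = None) -> float:
    """Static dipolar constant (Hz) for a coupling type.

    ``Dmax = -mu0 * hbar * gamma_i * gamma_j / (8 pi^2 r^3)`` so that the
    observed coupling is ``Dmax * u^T S u`` (the quadratic form already
    carries the P2 angular factor).  For H-N at the default 1.041 A
    effective length this evaluates to about -10.7 kHz.
    """
    if coupling_type not in COUPLING_TYPES:
        raise KeyError(f"unknown coupling type {coupling_type!r}")
    _ai, _aj, ei, ej = COUPLING_TYPES[coupling_type]
    r = (EFFECTIVE_BOND_LENGTHS[coupling_type]
         if effective_bond_length is None else effective_bond_length) * 1e-10
    b = -(constants.mu_0 * constants.hbar * _GAMMA[ei] * _GAMMA[ej]
          / (4.0 * np.pi * r ** 3))
    return float(b / (2.0 * np.pi))


@dataclass
class RDCRecord:
    """One measured or predicted coupling."""

    residue_number: int
    coupling_type: str
    value: float                    # Hz
    uncertainty: float | None = None

    def __post_init__(self) -> None:
        if self.coupling_type not in COUPLING_TYPES:
            raise ValueError(f"unknown coupling type {self.coupling_type!r}")
        if not np.isfinite(self.value):
            raise ValueError("RDC value must be finite")

    @property
    def atoms(self) -> tuple[tuple[str, int], tuple[str, int]]:
        """Resolved (atom_name, residue offset) pair for this coupling."""
        ai, aj, _ei, _ej = COUPLING_TYPES[self.coupling_type]
        return ai, aj


@dataclass
class SaupeTensor:
    """Symmetric traceless order matrix via its 5 independent elements.

    The element convention is ``(Szz, Sxx - Syy, Sxy, Sxz, Syz)``.
    Principal values are sorted by descending magnitude |Szz'| >= |Syy'|
    >= |Sxx'|; the magnitude is Szz' and the rhombicity
    ``R = (2/3)(Sxx' - Syy')/Szz'`` lies in [0, 2/3].
    """

    independent_elements: np.ndarray

    def __post_init__(self) -> None:
        self.independent_elements = np.asarray(self.independent_elements, dtype=float)
        if self.independent_elements.shape != (5,):
            raise ValueError("need exactly 5 independent elements")

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "SaupeTensor":
        m = np.asarray(matrix, dtype=float)
        if not np.allclose(m, m.T, atol=1e-9) or abs(np.trace(m)) > 1e-9:
            raise ValueError("matrix must be symmetric and traceless")
        return cls(np.array([m[2, 2], m[0, 0] - m[1, 1], m[0, 1], m[0, 2], m[1, 2]]))

    @property
    def matrix(self) -> np.ndarray:
        szz, d, sxy, sxz, syz = self.independent_elements
        sxx = (d - szz) / 2.0
        syy = (-d - szz) / 2.0
        return np.array([[sxx, sxy, sxz],
                         [sxy, syy, syz],
                         [sxz, syz, szz]])

    def _principal(self) -> tuple[np.ndarray, np.ndarray]:
        w, v = np.linalg.eigh(self.matrix)
        order = np.argsort(np.abs(w))[::-1]
        return w[order], v[:, order]

    @property
    def principal_values(self) -> np.ndarray:
        return self._principal()[0]

    @property
    def principal_axes(self) -> np.ndarray:
        """Columns are the z', y', x' principal axes (descending |value|)."""
        return self._principal()[1]

    @property
    def magnitude(self) -> float:
        """Largest-|.| principal value Szz' (the axial order parameter)."""
        return float(self.principal_values[0])

    @property
    def rhombicity(self) -> float:
        szz, syy, sxx = self.principal_values
        return float((2.0 / 3.0) * (sxx - syy) / szz)


@dataclass
class RDCFitResult:
    tensor: SaupeTensor
    records: list[RDCRecord]
    predicted: np.ndarray
    residuals: np.ndarray
    pearson_r: float
    q_factor: float
    rmsd: float
    outlier_flags: np.ndarray
    n_structures_used: int
    seed: int | None = None
    per_type: dict[str, dict[str, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Splittings and tables
# ---------------------------------------------------------------------------

def splittings_to_rdc(iso_table: pd.DataFrame, aniso_table: pd.DataFrame,
                      flip_sign: bool = False) -> list[RDCRecord]:
    """Difference anisotropic - isotropic doublet splittings into RDCs.

    Both tables need columns ``residue``, ``type``, ``splitting_hz``.
    The default convention is ``D = splitting_aniso - splitting_iso``;
    ``flip_sign`` negates every value for the opposite convention.
    Unmatched (residue, type) keys are reported and dropped.
    """
    records = []
    for table, name in ((iso_table, "isotropic"), (aniso_table, "anisotropic")):
        if table.duplicated(subset=["residue", "type"]).any():
            raise ValueError(f"duplicate (residue, type) keys in the {name} table")
    merged = iso_table.merge(aniso_table, on=["residue", "type"],
                             suffixes=("_iso", "_aniso"), how="outer", indicator=True)
    unmatched = merged[merged["_merge"] != "both"]
    if len(unmatched):
        logger.warning("dropping %d unmatched splitting keys: %s", len(unmatched),
                       list(zip(unmatched["residue"], unmatched["type"])))
    sign = -1.0 if flip_sign else 1.0
    for _, row in merged[merged["_merge"] == "both"].iterrows():
        value = sign * (row["splitting_hz_aniso"] - row["splitting_hz_iso"])
        records.append(RDCRecord(int(row["residue"]), str(row["type"]), float(value)))
    return records


def read_rdc_table(path: str | Path) -> list[RDCRecord]:
    """Read a TSV with columns residue, type, value_hz[, sigma_hz]."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        sigma = float(row["sigma_hz"]) if "sigma_hz" in df.columns and \
            np.isfinite(row.get("sigma_hz", np.nan)) else None
        records.append(RDCRecord(int(row["residue"]), str(row["type"]),
                                 float(row["value_hz"]), sigma))
    return records


def write_rdc_table(records: list[RDCRecord], path: str | Path) -> None:
    rows = [{"residue": r.residue_number, "type": r.coupling_type,
             "value_hz": r.value,
             "sigma_hz": np.nan if r.uncertainty is None else r.uncertainty}
            for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _build_amide_h(frame: Frame, chain: str, resnum: int) -> np.ndarray:
    """Place the amide H on the peptide plane, opposite the C(i-1)/CA bisector."""
    n = frame.atom(chain, resnum, "N").position
    ca = frame.atom(chain, resnum, "CA").position
    c_prev = frame.atom(chain, resnum - 1, "C").position
    d1 = n - c_prev
    d2 = n - ca
    d = d1 / np.linalg.norm(d1) + d2 / np.linalg.norm(d2)
    return n + EFFECTIVE_BOND_LENGTHS["H-N"] * d / np.linalg.norm(d)


def _build_alpha_h(frame: Frame, chain: str, resnum: int) -> np.ndarray:
    """Tetrahedral HA opposite the mean of the N, C, CB directions."""
    ca = frame.atom(chain, resnum, "CA").position
    d = np.zeros(3)
    for name in ("N", "C", "CB"):
        p = frame.atom(chain, resnum, name).position
        u = p - ca
        d += u / np.linalg.norm(u)
    return ca - EFFECTIVE_BOND_LENGTHS["CA-HA"] * d / np.linalg.norm(d)


def _atom_position(frame: Frame, chain: str, resnum: int, name: str) -> np.ndarray:
    if frame.has_atom(chain, resnum, name):
        return frame.atom(chain, resnum, name).position
    if name == "H":
        return _build_amide_h(frame, chain, resnum)
    if name == "HA":
        return _build_alpha_h(frame, chain, resnum)
    raise MissingAtomError(f"atom {name} of residue {resnum} unresolvable")


def bond_unit_vectors(frame: Frame, records: list[RDCRecord],
                      chain: str | None = None) -> np.ndarray:
    """Per-record unit internuclear vectors for one frame.

    Heavy atoms come from the coordinates; amide and alpha hydrogens are
    constructed geometrically when absent (the usual case for crystal and
    backbone-only models).
    """
    if chain is None:
        chain = frame.chains()[0]
    out = np.empty((len(records), 3))
    for i, rec in enumerate(records):
        (a1, off1), (a2, off2) = rec.atoms
        p1 = _atom_position(frame, chain, rec.residue_number + off1, a1)
        p2 = _atom_position(frame, chain, rec.residue_number + off2, a2)
        d = p2 - p1
        out[i] = d / np.linalg.norm(d)
    return out


def _quadratic_form_rows(u: np.ndarray) -> np.ndarray:
    """Design-matrix coefficients of u^T S u in the 5-element convention."""
    ux, uy, uz = u[:, 0], u[:, 1], u[:, 2]
    return np.stack([(3.0 * uz ** 2 - 1.0) / 2.0,
                     (ux ** 2 - uy ** 2) / 2.0,
                     2.0 * ux * uy,
                     2.0 * ux * uz,
                     2.0 * uy * uz], axis=1)


def _design_matrix(frames: list[Frame], records: list[RDCRecord],
                   chain: str | None) -> np.ndarray:
    scale = np.array([dmax(r.coupling_type) for r in records])
    acc = np.zeros((len(records), 5))
    for frame in frames:
        u = bond_unit_vectors(frame, records, chain)
        acc += _quadratic_form_rows(u)
    acc /= len(frames)
    return acc * scale[:, None]


def predict_rdc(frames: Ensemble | Frame, tensor: SaupeTensor,
                records: list[RDCRecord], chain: str | None = None) -> np.ndarray:
    """Ensemble-averaged couplings ``Dmax * <u^T S u>`` (Hz)."""
    frame_list = [frames] if isinstance(frames, Frame) else frames.frames
    A = _design_matrix(frame_list, records, chain)
    return A @ tensor.independent_elements


# ---------------------------------------------------------------------------
# SVD fit and scoring
# ---------------------------------------------------------------------------

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt((da @ da) * (db @ db))
    return float(da @ db / denom) if denom > 0 else float("nan")


def svd_fit(ensemble: Ensemble | Frame, records: list[RDCRecord],
            max_structures: int = 100, seed: int | None = 2024,
            chain: str | None = None,
            use_uncertainty_weights: bool = False) -> RDCFitResult:
    """Fit one alignment tensor to all records over an ensemble by SVD.

    All frames are fitted simultaneously: the design matrix holds
    frame-averaged orientational coefficients, so a single tensor and an
    ensemble-averaged prediction come out of one linear least-squares
    solve.  If the ensemble exceeds ``max_structures`` frames, a uniform
    random subset of that size is drawn (without replacement) with the
    given seed.  Records are unweighted by default.
    """
    if len(records) < 5:
        raise ValueError("need at least 5 records to determine 5 tensor elements")
    if isinstance(ensemble, Frame):
        frames = [ensemble]
    else:
        frames = ensemble.frames
    if len(frames) > max_structures:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(frames), size=max_structures, replace=False))
        frames = [frames[i] for i in idx]

    A = _design_matrix(frames, records, chain)
    obs = np.array([r.value for r in records])
    if use_uncertainty_weights:
        w = np.array([1.0 / r.uncertainty if r.uncertainty else 1.0 for r in records])
        A_w, obs_w = A * w[:, None], obs * w
    else:
        A_w, obs_w = A, obs
    if np.linalg.matrix_rank(A_w, tol=1e-10 * max(1.0, np.abs(A_w).max())) < 5:
        raise DegenerateFitError("design matrix is rank-deficient; "
                                 "bond vectors do not span enough orientations")
    elements, *_ = np.linalg.lstsq(A_w, obs_w, rcond=None)
    tensor = SaupeTensor(elements)
    predicted = A @ elements
    residuals = obs - predicted
    rms_obs = float(np.sqrt(np.mean(obs ** 2)))
    rmsd = float(np.sqrt(np.mean(residuals ** 2)))
    per_type: dict[str, dict[str, float]] = {}
    for ct in sorted({r.coupling_type for r in records}):
        mask = np.array([r.coupling_type == ct for r in records])
        entry = {"n": int(mask.sum()),
                 "rmsd": float(np.sqrt(np.mean(residuals[mask] ** 2)))}
        if mask.sum() >= 3:
            entry["pearson_r"] = _pearson(obs[mask], predicted[mask])
        per_type[ct] = entry
    result = RDCFitResult(
        tensor=tensor,
        records=records,
        predicted=predicted,
        residuals=residuals,
        pearson_r=_pearson(obs, predicted),
        q_factor=rmsd / rms_obs if rms_obs > 0 else float("nan"),
        rmsd=rmsd,
        outlier_flags=np.zeros(len(records), dtype=bool),
        n_structures_used=len(frames),
        seed=seed,
        per_type=per_type,
    )
    result.outlier_flags = _outlier_mask(result.residuals, 2.0)
    return result


def correlation_curve(ensemble: Ensemble, records: list[RDCRecord],
                      sizes: list[int], seed: int = 2024,
                      type_filter: str | None = None,
                      chain: str | None = None) -> dict[int, float]:
    """Pearson r between observed and back-calculated RDCs vs ensemble size.

    For each size a random frame subset is drawn and the tensor is fitted
    over *all* records; the correlation is optionally reported on one
    coupling-type subset only.  Using the full ensemble size implies no
    resampling, so repeated calls return identical values.
    """
    n = len(ensemble.frames)
    out: dict[int, float] = {}
    for size in sizes:
        if size > n:
            raise ValueError(f"requested size {size} exceeds ensemble size {n}")
        if size == n:
            sub = ensemble
        else:
            rng = np.random.default_rng([seed, size])
            idx = np.sort(rng.choice(n, size=size, replace=False))
            sub = ensemble.subset(idx)
        fit = svd_fit(sub, records, max_structures=size, seed=seed, chain=chain)
        if type_filter is None:
            out[size] = fit.pearson_r
        else:
            mask = np.array([r.coupling_type == type_filter for r in records])
            obs = np.array([r.value for r in records])
            out[size] = _pearson(obs[mask], fit.predicted[mask])
    return out


def _outlier_mask(residuals: np.ndarray, threshold_sd: float) -> np.ndarray:
    sd = float(np.std(residuals))
    if sd == 0.0:
        return np.zeros(len(residuals), dtype=bool)
    return np.abs(residuals) > threshold_sd * sd


def flag_outliers(result: RDCFitResult, threshold_sd: float = 2.0) -> list[int]:
    """Residue numbers whose |residual| exceeds ``threshold_sd`` residual SDs."""
    if len(result.records) < 3:
        raise ValueError("need at least 3 records")
    mask = _outlier_mask(result.residuals, threshold_sd)
    return [r.residue_number for r, m in zip(result.records, mask) if m]
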