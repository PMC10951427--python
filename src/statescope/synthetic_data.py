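"""Synthetic ensembles and RDC datasets with known ground truth.

Every analysis stage in this package can be exercised against data whose
generating parameters are known exactly:

* a deterministic *toy domain* — a small three-strand antiparallel
  beta-sheet plus one alpha-helix with chemically sane backbone geometry,
  carrying designated "pY loop" and "+5 site" residue ranges;
* two-state conformational ensembles mixing an alpha-like endpoint
  (spread sheet, closed pY loop, closed +5 site) and a beta-like endpoint
  (zipped sheet, open pY loop, open +5 site) with Gaussian thermal noise;
* RDC tables generated from a known Saupe tensor with Gaussian
  measurement noise;
* crystal *stand-in* structures whose descriptor atoms are placed at
  prescribed distances (synthetic geometry, not deposited coordinates);
* a toy structure-survey set with planted screening defects.

The geometry is a stand-in: no force field, no physics — just enough
structure (ideal backbone bonds, genuine beta-sheet hydrogen bonds, a
real helix) for the secondary-structure, alignment, PCA and RDC
machinery to operate on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .ensemble_io import AtomSite, Ensemble, Frame, ResidueRangeSet
from .rdc_analysis import RDCRecord, SaupeTensor, predict_rdc

__all__ = [
    "TwoStateSpec",
    "RDCSimSpec",
    "ToyLayout",
    "toy_layout",
    "make_toy_domain",
    "make_endpoint_pair",
    "make_two_state_ensemble",
    "make_synthetic_rdcs",
    "make_distance_standin",
    "make_survey_entry_set",
    "DEFAULT_TRUE_TENSOR",
]

# Ideal backbone internal coordinates (A, degrees).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
_STRAND_PHI, _STRAND_PSI = -139.0, 135.0
_HELIX_PHI, _HELIX_PSI = -57.0, -47.0
_HBOND_NO = 2.95     # target N...O distance for designed sheet bridges, A

#: Default true alignment tensor for RDC simulations (order ~1e-3, giving
#: couplings of a few Hz to tens of Hz, as for a weakly aligned protein).
DEFAULT_TRUE_TENSOR = SaupeTensor(np.array([8.0e-4, 3.0e-4, 1.2e-4, -0.9e-4, 0.6e-4]))


# ---------------------------------------------------------------------------
# NeRF backbone construction
# ---------------------------------------------------------------------------

def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension placement of D from the A-B-C internal frame."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(angle),
                        bond * np.sin(angle) * np.cos(torsion),
                        bond * np.sin(angle) * np.sin(torsion)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    x = v @ w
    y = np.cross(b1n, v) @ w
    return float(np.degrees(np.arctan2(y, x)))


class _BackboneBuilder:
    """Incremental N/CA/C backbone builder with fixed ideal geometry."""

    def __init__(self) -> None:
        self.N: list[np.ndarray] = []
        self.CA: list[np.ndarray] = []
        self.C: list[np.ndarray] = []

    def start(self) -> None:
        self.N.append(np.zeros(3))
        self.CA.append(np.array([_B_N_CA, 0.0, 0.0]))
        ang = np.deg2rad(180.0 - _A_N_CA_C)
        self.C.append(self.CA[-1] + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0]))

    def extend(self, psi_prev: float, phi: float) -> None:
        """Append one residue given psi of the previous residue and its phi."""
        n_new = _place_atom(self.N[-1], self.CA[-1], self.C[-1],
                            _B_C_N, _A_CA_C_N, psi_prev)
        ca_new = _place_atom(self.CA[-1], self.C[-1], n_new,
                             _B_N_CA, _A_C_N_CA, 180.0)
        c_new = _place_atom(self.C[-1], n_new, ca_new,
                            _B_CA_C, _A_N_CA_C, phi)
        self.N.append(n_new)
        self.CA.append(ca_new)
        self.C.append(c_new)

    def append_fixed(self, n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> None:
        self.N.append(np.asarray(n, float))
        self.CA.append(np.asarray(ca, float))
        self.C.append(np.asarray(c, float))

    def copy(self) -> "_BackboneBuilder":
        b = _BackboneBuilder()
        b.N = [p.copy() for p in self.N]
        b.CA = [p.copy() for p in self.CA]
        b.C = [p.copy() for p in self.C]
        return b


def _build_segment(n_res: int, phi: float, psi: float) -> _BackboneBuilder:
    b = _BackboneBuilder()
    b.start()
    for _ in range(1, n_res):
        b.extend(psi, phi)
    return b


def _strand_oxygens(b: _BackboneBuilder, final_psi: float) -> np.ndarray:
    out = []
    for i in range(len(b.N)):
        if i < len(b.N) - 1:
            psi = _dihedral(b.N[i], b.CA[i], b.C[i], b.N[i + 1])
        else:
            psi = final_psi
        out.append(_place_atom(b.N[i], b.CA[i], b.C[i], _B_C_O, _A_CA_C_O, psi - 180.0))
    return np.array(out)


def _canonical_strand(n_res: int) -> dict[str, np.ndarray]:
    """Ideal strand oriented along +x with carbonyls in the sheet (xy) plane.

    CA(1) sits at the origin; the CA(1)->CA(last) axis points along +x;
    the roll is fixed so the first carbonyl C->O direction lies in the
    +y half of the xy-plane (carbonyls then alternate +y/-y along the
    strand, as in a flat beta-sheet).
    """
    b = _build_segment(n_res, _STRAND_PHI, _STRAND_PSI)
    coords = {"N": np.array(b.N), "CA": np.array(b.CA), "C": np.array(b.C),
              "O": _strand_oxygens(b, _STRAND_PSI)}
    origin = coords["CA"][0].copy()
    for key in coords:
        coords[key] = coords[key] - origin
    axis = coords["CA"][-1] / np.linalg.norm(coords["CA"][-1])
    target = np.array([1.0, 0.0, 0.0])
    v = np.cross(axis, target)
    s = np.linalg.norm(v)
    c = float(axis @ target)
    if s < 1e-12:
        R1 = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R1 = np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)
    for key in coords:
        coords[key] = coords[key] @ R1.T
    co = coords["O"][0] - coords["C"][0]
    roll = np.arctan2(co[2], co[1])           # rotate C->O into the +y plane
    cr, sr = np.cos(-roll), np.sin(-roll)
    R2 = np.array([[1.0, 0, 0], [0, cr, -sr], [0, sr, cr]])
    for key in coords:
        coords[key] = coords[key] @ R2.T
    return coords


def _rot_z_pi_about(x0: float, y0: float) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform: rotate pi about the z-parallel axis through (x0, y0)."""
    R = np.diag([-1.0, -1.0, 1.0])
    t = np.array([2.0 * x0, 2.0 * y0, 0.0])
    return R, t


def _transform_coords(coords: dict[str, np.ndarray], R: np.ndarray,
                      t: np.ndarray) -> dict[str, np.ndarray]:
    return {k: v @ R.T + t for k, v in coords.items()}


def _carbonyl_parity(template: dict[str, np.ndarray], positive: bool) -> list[int]:
    """Interior residue indices whose C=O points to +y (or -y)."""
    out = []
    n = len(template["CA"])
    for i in range(n):
        dy = template["O"][i][1] - template["C"][i][1]
        if (dy > 0) == positive:
            out.append(i)
    return out


def _pair_transform(template: dict[str, np.ndarray], side: int
                    ) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Antiparallel-partner transform for one side of the template strand.

    ``side`` is +1 (partner toward +y) or -1.  Narrow bridge pairs (i, j)
    — the pairs carrying both N-H...O=C bonds — are those where both
    carbonyls point toward the partner; under the two-fold construction
    they satisfy i + j = constant with matching parity.  The two-fold
    axis position (x0, y0) is refined by least squares so each designated
    pair reaches the target N...O distance in both directions.
    """
    n = len(template["CA"])
    donors = _carbonyl_parity(template, positive=(side > 0))
    # one registry constant c: narrow pairs are (i, c - i); pick the c that
    # yields the most designated pairs (both partners' carbonyls face in)
    best_c, best_pairs = None, []
    for c in range(n + 2):
        pairs = sorted({tuple(sorted((i, c - i))) for i in donors
                        if 0 <= c - i < n and (c - i) in donors})
        if len(pairs) > len(best_pairs):
            best_c, best_pairs = c, pairs
    if not best_pairs:
        raise ValueError("no bridge pairs available for this strand length")
    pairs = best_pairs
    x_guess = float(np.mean([template["CA"][i][0] + template["CA"][j][0]
                             for i, j in pairs])) / 2.0
    y_guess = side * 2.4

    def transform(p):
        R, t = _rot_z_pi_about(p[0], p[1])
        return R, t + np.array([0.0, 0.0, p[2]])

    def _amide_h(coords, i):
        n_pos, ca, c_prev = coords["N"][i], coords["CA"][i], coords["C"][i - 1]
        d1 = n_pos - c_prev
        d2 = n_pos - ca
        d = d1 / np.linalg.norm(d1) + d2 / np.linalg.norm(d2)
        return n_pos + 1.01 * d / np.linalg.norm(d)

    def residual(p):
        # target near-linear N-H...O=C bonds: O...N = 2.95 and O...H = 1.95
        R, t = transform(p)
        other = _transform_coords(template, R, t)
        res = []
        for i, j in pairs:
            if j >= 1:      # donor N-H on the partner, acceptor C=O on template
                h = _amide_h(other, j)
                res.append(np.linalg.norm(template["O"][i] - other["N"][j]) - _HBOND_NO)
                res.append(np.linalg.norm(template["O"][i] - h) - (_HBOND_NO - 1.0))
            if i >= 1:      # donor N-H on the template, acceptor C=O on partner
                h = _amide_h(template, i)
                res.append(np.linalg.norm(other["O"][j] - template["N"][i]) - _HBOND_NO)
                res.append(np.linalg.norm(other["O"][j] - h) - (_HBOND_NO - 1.0))
        return res

    y_lo, y_hi = (1.8, 3.2) if side > 0 else (-3.2, -1.8)
    sol = least_squares(residual, x0=np.array([x_guess, y_guess, 0.0]),
                        bounds=([x_guess - 4.0, y_lo, -2.0],
                                [x_guess + 4.0, y_hi, 2.0]),
                        method="trf", xtol=1e-14, ftol=1e-14)
    R, t = transform(sol.x)
    return R, t, pairs


# ---------------------------------------------------------------------------
# Toy domain layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyLayout:
    """Residue ranges (author numbering) of the toy fold's segments."""

    strand_a: tuple[int, int]
    py_loop: tuple[int, int]        # 8 residues, like Ser34-Phe41
    strand_b: tuple[int, int]
    turn: tuple[int, int]
    strand_c: tuple[int, int]
    plus5_loop: tuple[int, int]
    helix: tuple[int, int]
    tail: tuple[int, int]
    spread_pair: tuple[tuple[int, str], tuple[int, str]]

    @property
    def py_loop_range(self) -> ResidueRangeSet:
        return ResidueRangeSet([self.py_loop])

    @property
    def plus5_range(self) -> ResidueRangeSet:
        last = self.helix[1] if self.helix[1] >= self.helix[0] else self.plus5_loop[1]
        return ResidueRangeSet([(self.plus5_loop[0], last)])

    @property
    def core_range(self) -> ResidueRangeSet:
        """Rigid core: strands A and B, static across the two states."""
        return ResidueRangeSet([self.strand_a, self.strand_b])

    @property
    def sheet_range(self) -> ResidueRangeSet:
        return ResidueRangeSet([self.strand_a, self.strand_b, self.strand_c])

    @property
    def full_range(self) -> ResidueRangeSet:
        return ResidueRangeSet([(self.strand_a[0], self.tail[1])])


_N_LOOP_PY = 8
_N_TURN = 4
_N_LOOP5 = 4


def toy_layout(n_residues: int, first_residue_number: int = 1) -> ToyLayout:
    if n_residues < 20:
        raise ValueError("toy domain needs at least 20 residues")
    if n_residues >= 40:
        ns, n_turn, n_loop5 = 6, _N_TURN, _N_LOOP5
    elif n_residues >= 30:
        ns, n_turn, n_loop5 = 4, _N_TURN, _N_LOOP5
    else:
        ns, n_turn, n_loop5 = 3, 2, 1
    fixed = 3 * ns + _N_LOOP_PY + n_turn + n_loop5
    helix_len = max(0, min(12, n_residues - fixed))
    tail_len = n_residues - fixed - helix_len
    pos = first_residue_number

    def take(k):
        nonlocal pos
        rng = (pos, pos + k - 1)
        pos += k
        return rng

    strand_a = take(ns)
    py_loop = take(_N_LOOP_PY)
    strand_b = take(ns)
    turn = take(n_turn)
    strand_c = take(ns)
    plus5_loop = take(n_loop5)
    helix = take(helix_len) if helix_len else (pos, pos - 1)
    tail = take(tail_len) if tail_len else (pos, pos - 1)
    spread_pair = ((strand_b[1] - 1, "C"), (strand_c[0] + 1, "N"))
    return ToyLayout(strand_a, py_loop, strand_b, turn, strand_c,
                     plus5_loop, helix, tail, spread_pair)


# Residue-name cycle (no GLY/PRO: every residue gets a CB and an amide H).
_TOY_SEQ_CYCLE = ["ALA", "VAL", "LEU", "SER", "THR", "LYS", "GLU", "PHE",
                  "ILE", "ASN", "ASP", "TYR", "ARG", "GLN", "TRP", "MET"]


# ---------------------------------------------------------------------------
# Loop closure
# ---------------------------------------------------------------------------

def _closure_extend(builder: _BackboneBuilder, n_loop: int,
                    target: tuple[np.ndarray, np.ndarray, np.ndarray],
                    seed: int) -> None:
    """Grow ``n_loop`` residues whose dihedrals land on the target stub.

    Unknowns: psi of the current last residue, (phi, psi) of each loop
    residue, and phi of the landing residue; residuals are the positions
    of the landing residue's N, CA and C (the solve is deterministic:
    fixed start point, Levenberg-Marquardt).  The landing residue itself
    is *not* appended — its pre-placed coordinates are used by the caller.
    """
    base_len = len(builder.N)
    rng = np.random.default_rng(seed)
    x0 = np.empty(2 * n_loop + 2)
    x0[0] = _STRAND_PSI
    x0[1:-1] = np.where(np.arange(2 * n_loop) % 2 == 0, -80.0, 120.0) \
        + rng.uniform(-25.0, 25.0, 2 * n_loop)
    x0[-1] = _STRAND_PHI

    def simulate(params, commit=False):
        b = builder.copy()
        psis = [params[0]] + list(params[2:2 * n_loop + 1:2])
        phis = list(params[1:2 * n_loop:2]) + [params[-1]]
        for k in range(n_loop + 1):
            b.extend(psis[k], phis[k])
        if commit:
            return b
        return np.concatenate([b.N[-1] - target[0],
                               b.CA[-1] - target[1],
                               b.C[-1] - target[2]])

    best = None
    for attempt in range(8):
        sol = least_squares(simulate, x0=x0, method="trf", xtol=1e-15, ftol=1e-15,
                            gtol=1e-15, max_nfev=4000)
        if best is None or sol.cost < best.cost:
            best = sol
        if np.sqrt(2 * best.cost) < 1e-6:
            break
        x0 = x0.copy()
        x0[1:-1] = np.where(np.arange(2 * n_loop) % 2 == 0, -80.0, 120.0) \
            + rng.uniform(-60.0, 60.0, 2 * n_loop)
    solved = simulate(best.x, commit=True)
    builder.N[:] = solved.N[:base_len + n_loop]
    builder.CA[:] = solved.CA[:base_len + n_loop]
    builder.C[:] = solved.C[:base_len + n_loop]


# ---------------------------------------------------------------------------
# Toy domain assembly
# ---------------------------------------------------------------------------

def _assemble_backbone(layout: ToyLayout) -> _BackboneBuilder:
    ns = layout.strand_a[1] - layout.strand_a[0] + 1
    template = _canonical_strand(ns)
    # Strand B is the template (runs +x).  A and C are antiparallel
    # partners on the -y and +y sides; both run -x in space while their
    # own N->C order is preserved, which is exactly what the chain
    # A -> pY loop -> B -> turn -> C requires.
    R_a, t_a, _ = _pair_transform(template, side=-1)
    R_c, t_c, _ = _pair_transform(template, side=+1)
    strand_a = _transform_coords(template, R_a, t_a)
    strand_c = _transform_coords(template, R_c, t_c)

    builder = _BackboneBuilder()
    for i in range(ns):
        builder.append_fixed(strand_a["N"][i], strand_a["CA"][i], strand_a["C"][i])
    n_loop_py = layout.py_loop[1] - layout.py_loop[0] + 1
    _closure_extend(builder, n_loop_py,
                    (template["N"][0], template["CA"][0], template["C"][0]), seed=11)
    for i in range(ns):
        builder.append_fixed(template["N"][i], template["CA"][i], template["C"][i])
    n_turn = layout.turn[1] - layout.turn[0] + 1
    _closure_extend(builder, n_turn,
                    (strand_c["N"][0], strand_c["CA"][0], strand_c["C"][0]), seed=13)
    for i in range(ns):
        builder.append_fixed(strand_c["N"][i], strand_c["CA"][i], strand_c["C"][i])

    # +5 loop steering the helix away from the sheet, then helix and tail.
    loop5 = [(-80.0, 100.0), (-70.0, -30.0), (-100.0, 140.0), (-70.0, -35.0)]
    n_loop5 = layout.plus5_loop[1] - layout.plus5_loop[0] + 1
    psi_prev = _STRAND_PSI
    for phi, psi in loop5[:n_loop5]:
        builder.extend(psi_prev, phi)
        psi_prev = psi
    helix_len = layout.helix[1] - layout.helix[0] + 1
    for _ in range(helix_len):
        builder.extend(psi_prev, _HELIX_PHI)
        psi_prev = _HELIX_PSI
    tail_len = layout.tail[1] - layout.tail[0] + 1
    for _ in range(tail_len):
        builder.extend(psi_prev, -100.0)
        psi_prev = 130.0
    return builder


from functools import lru_cache


@lru_cache(maxsize=8)
def _toy_domain_cached(n_residues: int, fold: str, first_residue_number: int,
                       chain_id: str) -> Frame:
    return _make_toy_domain_impl(n_residues, fold, first_residue_number, chain_id)


def make_toy_domain(n_residues: int = 64, fold: str = "helix_sheet_toy",
                    first_residue_number: int = 1,
                    chain_id: str = "A") -> Frame:
    """Deterministic toy fold: three-strand antiparallel sheet plus helix.

    The backbone (N, CA, CB, C, O) is built from ideal internal
    coordinates; the three strands form a genuine antiparallel sheet
    (their inter-strand N-H...O=C bonds satisfy the Kabsch-Sander
    criterion) and the connecting loops are closed by a deterministic
    least-squares solve over their dihedrals.  Identical arguments give
    bit-identical coordinates (results are memoised; a fresh copy is
    returned each call).
    """
    return _toy_domain_cached(n_residues, fold, first_residue_number, chain_id).copy()


def _make_toy_domain_impl(n_residues: int = 64, fold: str = "helix_sheet_toy",
                          first_residue_number: int = 1,
                          chain_id: str = "A") -> Frame:
    """Deterministic toy fold: three-strand antiparallel sheet plus helix.

    The backbone (N, CA, CB, C, O) is built from ideal internal
    coordinates; the three strands form a genuine antiparallel sheet
    (their inter-strand N-H...O=C bonds satisfy the Kabsch-Sander
    criterion) and the connecting loops are closed by a deterministic
    least-squares solve over their dihedrals.  Identical arguments give
    bit-identical coordinates.
    """
    if fold != "helix_sheet_toy":
        raise ValueError(f"unknown fold {fold!r}")
    layout = toy_layout(n_residues, first_residue_number)
    builder = _assemble_backbone(layout)
    n = len(builder.N)
    assert n == n_residues

    sites: list[AtomSite] = []
    for i in range(n):
        resnum = first_residue_number + i
        resname = _TOY_SEQ_CYCLE[i % len(_TOY_SEQ_CYCLE)]
        N, CA, C = builder.N[i], builder.CA[i], builder.C[i]
        psi = (_dihedral(N, CA, C, builder.N[i + 1]) if i < n - 1 else 135.0)
        O = _place_atom(N, CA, C, _B_C_O, _A_CA_C_O, psi - 180.0)
        u_n = (N - CA) / np.linalg.norm(N - CA)
        u_c = (C - CA) / np.linalg.norm(C - CA)
        bis = -(u_n + u_c)
        bis /= np.linalg.norm(bis)
        perp = np.cross(u_c, u_n)
        perp /= np.linalg.norm(perp)
        CB = CA + _B_CA_CB * (np.cos(0.955) * bis + np.sin(0.955) * perp)
        for name, pos in (("N", N), ("CA", CA), ("CB", CB), ("C", C), ("O", O)):
            sites.append(AtomSite(chain_id, resnum, resname, name, pos))
    return Frame(sites, 0)


# ---------------------------------------------------------------------------
# Two-state ensembles
# ---------------------------------------------------------------------------

@dataclass
class TwoStateSpec:
    """Mixture of two conformational endpoints with Gaussian noise."""

    endpoint_a: Frame               # alpha-like: spread sheet, closed pY/+5
    endpoint_b: Frame               # beta-like: zipped sheet, open pY/+5
    fraction_a: float = 0.5
    noise_sd: float = 0.3           # A per coordinate
    n_frames: int = 200
    seed: int = 2024

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_a <= 1.0:
            raise ValueError("fraction_a must lie in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        keys_a = {s.key for s in self.endpoint_a.sites}
        keys_b = {s.key for s in self.endpoint_b.sites}
        if keys_a != keys_b:
            raise ValueError("endpoints must share one topology")


def make_endpoint_pair(n_residues: int = 64, first_residue_number: int = 1,
                       spread_shift: float = 3.0, py_shift: float = 1.5,
                       plus5_shift: float = 2.0) -> tuple[Frame, Frame, ToyLayout]:
    """Alpha-like and beta-like endpoints of the toy domain.

    The beta-like endpoint is the toy domain as built (zipped sheet).
    The alpha-like endpoint displaces the edge strand C outward by
    ``spread_shift`` (sheet spreading, ~3 A of the ~4->12 A range), the
    pY loop by ``py_shift`` toward closure, and the +5 segment by
    ``plus5_shift`` toward closure.  Magnitudes are synthetic design
    choices recorded here, not measured quantities.
    """
    layout = toy_layout(n_residues, first_residue_number)
    beta = make_toy_domain(n_residues, first_residue_number=first_residue_number)
    spread_dir = np.array([0.0, 1.0, 0.0])       # strand C sits on the +y side
    py_dir = np.array([0.0, 0.0, 1.0])
    plus5_dir = np.array([0.0, 0.0, 1.0])
    sites = []
    spread_set = ResidueRangeSet([layout.strand_c])
    for s in beta.sites:
        pos = s.position.copy()
        if s.residue_number in spread_set:
            pos = pos + spread_shift * spread_dir
        if s.residue_number in layout.py_loop_range:
            pos = pos + py_shift * py_dir
        if s.residue_number in layout.plus5_range:
            pos = pos + plus5_shift * plus5_dir
        sites.append(AtomSite(s.chain_id, s.residue_number, s.residue_name,
                              s.atom_name, pos))
    alpha = Frame(sites, 0)
    return alpha, beta, layout


def make_two_state_ensemble(spec: TwoStateSpec) -> tuple[Ensemble, list[str]]:
    """Frames drawn Bernoulli(fraction_a) from the endpoints, plus labels.

    Each frame is its endpoint plus i.i.d. Gaussian coordinate noise; the
    returned labels ("alpha"/"beta") are the generating states.
    """
    rng = np.random.default_rng(spec.seed)
    frames: list[Frame] = []
    labels: list[str] = []
    for fi in range(spec.n_frames):
        take_a = rng.random() < spec.fraction_a
        base = spec.endpoint_a if take_a else spec.endpoint_b
        labels.append("alpha" if take_a else "beta")
        sites = [AtomSite(s.chain_id, s.residue_number, s.residue_name, s.atom_name,
                          s.position + rng.normal(0.0, spec.noise_sd, 3))
                 for s in base.sites]
        frames.append(Frame(sites, fi))
    return Ensemble(frames, source_label=f"two-state seed={spec.seed}"), labels


# ---------------------------------------------------------------------------
# Synthetic RDC datasets
# ---------------------------------------------------------------------------

@dataclass
class RDCSimSpec:
    tensor: SaupeTensor = None  # type: ignore[assignment]
    noise_sd: float = 0.0       # Hz
    coupling_types: tuple[str, ...] = ("H-N",)
    seed: int = 2024

    def __post_init__(self) -> None:
        if self.tensor is None:
            self.tensor = DEFAULT_TRUE_TENSOR
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _resolvable_records(frame: Frame, chain: str,
                        coupling_types: tuple[str, ...]) -> list[RDCRecord]:
    residues = sorted({s.residue_number for s in frame.sites if s.chain_id == chain})
    first = residues[0]
    records = []
    for ct in coupling_types:
        for r in residues:
            needs_prev = ct in ("H-N", "N-C'", "H-C'")
            if needs_prev and (r - 1) not in residues:
                continue
            if r == first:
                continue
            records.append(RDCRecord(r, ct, 0.0))
    return records


def make_synthetic_rdcs(ensemble: Ensemble, spec: RDCSimSpec,
                        chain: str | None = None
                        ) -> tuple[list[RDCRecord], dict]:
    """Ensemble-averaged couplings under a known tensor, plus noise.

    Returns the records (values in Hz) and truth metadata carrying the
    generating tensor, noise level and seed.
    """
    if chain is None:
        chain = ensemble.first_chain()
    records = _resolvable_records(ensemble.frames[0], chain, spec.coupling_types)
    clean = predict_rdc(ensemble, spec.tensor, records, chain)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, len(records)) if spec.noise_sd > 0 \
        else np.zeros(len(records))
    out = [RDCRecord(r.residue_number, r.coupling_type, float(v + e),
                     spec.noise_sd if spec.noise_sd > 0 else None)
           for r, v, e in zip(records, clean, noise)]
    truth = {"tensor": spec.tensor, "noise_sd": spec.noise_sd, "seed": spec.seed,
             "clean_values": clean}
    return out, truth


# ---------------------------------------------------------------------------
# Crystal stand-ins and survey fixtures
# ---------------------------------------------------------------------------

def make_distance_standin(distances: dict[str, float], label: str = "standin",
                          chain_id: str = "A") -> Frame:
    """Synthetic stand-in for a crystal structure with given descriptor geometry.

    Builds a 101-residue toy fold numbered 3-103 (so the reference
    descriptor residues 35/39/42/58/66/67/88/89 exist) and then moves the
    second atom of each descriptor pair along the pair axis until the
    four diagnostic distances equal ``distances`` exactly.  This is
    synthetic geometry standing in for deposited coordinates — only the
    four descriptor distances are meaningful.
    """
    from .descriptors import KEY_DISTANCE_ATOMS
    frame = make_toy_domain(101, first_residue_number=3, chain_id=chain_id)
    positions = {s.key: s.position.copy() for s in frame.sites}
    for name, ((r1, a1), (r2, a2)) in KEY_DISTANCE_ATOMS.items():
        if name not in distances:
            raise KeyError(f"missing target distance for {name}")
        k1 = (chain_id, r1, "", a1)
        k2 = (chain_id, r2, "", a2)
        p1, p2 = positions[k1], positions[k2]
        axis = p2 - p1
        axis /= np.linalg.norm(axis)
        positions[k2] = p1 + float(distances[name]) * axis
    sites = [AtomSite(s.chain_id, s.residue_number, s.residue_name, s.atom_name,
                      positions[s.key]) for s in frame.sites]
    return Frame(sites, 0)


def _jittered_copy(frame: Frame, rng: np.random.Generator, sd: float = 0.05,
                   rotate: bool = True) -> Frame:
    from scipy.spatial.transform import Rotation
    R = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix() \
        if rotate else np.eye(3)
    t = rng.uniform(-20.0, 20.0, 3)
    sites = [AtomSite(s.chain_id, s.residue_number, s.residue_name, s.atom_name,
                      R @ s.position + t + rng.normal(0.0, sd, 3))
             for s in frame.sites]
    return Frame(sites, frame.frame_index)


def make_survey_entry_set(seed: int = 7, n_residues: int = 64
                          ) -> tuple[Frame, ToyLayout, list[dict]]:
    """Ten toy survey entries with planted screening defects.

    Returns the reference toy domain, its layout, and a list of entry
    dicts with keys ``label``, ``ensemble``, ``method``,
    ``expected_included`` and ``expected_reason``:

    * entries 1-4: rigidly moved, lightly jittered copies (X-ray-like,
      one model) — included;
    * entries 5-6: NMR-like multi-model copies (3 and 5 models) — included;
    * entries 7-8: a pY-loop residue deleted / an extra residue inserted
      in the loop — excluded, reason ``py_loop_length``;
    * entries 9-10: a backbone atom of a descriptor residue removed —
      excluded, reason ``incomplete_backbone``.
    """
    rng = np.random.default_rng(seed)
    reference = make_toy_domain(n_residues)
    layout = toy_layout(n_residues)
    entries: list[dict] = []

    for k in range(4):
        frame = _jittered_copy(reference, rng)
        entries.append({"label": f"ok_xray_{k+1}", "method": "xray",
                        "ensemble": Ensemble([frame]),
                        "expected_included": True, "expected_reason": None})
    for k, n_models in enumerate((3, 5)):
        frames = [Frame(_jittered_copy(reference, rng, sd=0.3).sites, m)
                  for m in range(n_models)]
        entries.append({"label": f"ok_nmr_{k+1}", "method": "nmr",
                        "ensemble": Ensemble(frames),
                        "expected_included": True, "expected_reason": None})

    # deletion inside the pY loop -> 7-residue loop
    drop = layout.py_loop[0] + 3
    frame = _jittered_copy(reference, rng)
    short = Frame([s for s in frame.sites if s.residue_number != drop], 0)
    entries.append({"label": "short_py_loop", "method": "xray",
                    "ensemble": Ensemble([short]),
                    "expected_included": False,
                    "expected_reason": "py_loop_length"})

    # insertion inside the pY loop -> 9-residue loop (renumber the tail up)
    ins_after = layout.py_loop[0] + 3
    frame = _jittered_copy(reference, rng)
    sites = []
    for s in frame.sites:
        num = s.residue_number + 1 if s.residue_number > ins_after else s.residue_number
        sites.append(AtomSite(s.chain_id, num, s.residue_name, s.atom_name, s.position))
        if s.residue_number == ins_after and s.atom_name == "O":
            for name in ("N", "CA", "CB", "C", "O"):
                src = frame.atom(s.chain_id, ins_after, name)
                sites.append(AtomSite(s.chain_id, ins_after + 1, "ALA", name,
                                      src.position + np.array([0.4, 0.4, 0.4])))
    entries.append({"label": "long_py_loop", "method": "xray",
                    "ensemble": Ensemble([Frame(sites, 0)]),
                    "expected_included": False,
                    "expected_reason": "py_loop_length"})

    # missing backbone atoms on descriptor residues
    (r_c, _a_c), (r_n, a_n) = layout.spread_pair
    frame = _jittered_copy(reference, rng)
    gap = Frame([s for s in frame.sites
                 if not (s.residue_number == r_n and s.atom_name == a_n)], 0)
    entries.append({"label": "missing_spread_atom", "method": "nmr",
                    "ensemble": Ensemble([gap]),
                    "expected_included": False,
                    "expected_reason": "incomplete_backbone"})

    frame = _jittered_copy(reference, rng)
    mid_py = layout.py_loop[0] + 2
    gap2 = Frame([s for s in frame.sites
                  if not (s.residue_number == mid_py and s.atom_name == "CA")], 0)
    entries.append({"label": "missing_loop_ca", "method": "xray",
                    "ensemble": Ensemble([gap2]),
                    "expected_included": False,
                    "expected_reason": "incomplete_backbone"})

    return reference, layout, entries
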