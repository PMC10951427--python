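"""Structure superposition, secondary structure, and sequence alignment.

Provides the machinery used to put every structure into one common frame:

* a 3-state (H/E/C) secondary-structure assignment based on the
  Kabsch-Sander backbone hydrogen-bond energy,
* a global Needleman-Wunsch alignment with affine gaps whose per-position
  score blends BLOSUM62 residue similarity with a secondary-structure
  match term,
* least-squares (Kabsch) rigid-body fitting on a rigid-core selection,
* per-residue RMSF of a fitted ensemble.

The rigid core used throughout the SH2 analyses is the low-fluctuation
backbone: residues 7-33, 40-47, 50-58, 61-65, 71-81, 88-90, 95-101 of the
SHP2 N-SH2 domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from .ensemble_io import (
    Ensemble,
    Frame,
    MissingAtomError,
    ResidueRangeSet,
    frame_coordinates,
    select_coordinates,
)

__all__ = [
    "SequenceAlignment",
    "RigidTransform",
    "DegenerateGeometryError",
    "N_SH2_CORE",
    "assign_secondary_structure",
    "align_with_ss",
    "kabsch_fit",
    "superpose_ensemble",
    "rmsf",
]

#: Rigid-core residue ranges of the reference SH2 domain (author numbering).
N_SH2_CORE = ResidueRangeSet([(7, 33), (40, 47), (50, 58), (61, 65),
                              (71, 81), (88, 90), (95, 101)])

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

#: Secondary-structure match matrix: reward identical labels, penalise
#: helix/strand confusion, stay neutral against coil.
_SS_SCORE = {
    ("H", "H"): 6.0, ("E", "E"): 6.0, ("C", "C"): 6.0,
    ("H", "E"): -6.0, ("E", "H"): -6.0,
    ("H", "C"): 0.0, ("C", "H"): 0.0,
    ("E", "C"): 0.0, ("C", "E"): 0.0,
}


class DegenerateGeometryError(ValueError):
    """Point set too small or collinear for a rigid fit."""


# ---------------------------------------------------------------------------
# Kabsch-Sander secondary structure (3-state)
# ---------------------------------------------------------------------------

_HB_CUTOFF = -0.5      # kcal/mol
_Q1Q2F = 0.084 * 332.0  # Kabsch-Sander electrostatic prefactor, kcal*A/mol


def _backbone_by_residue(frame: Frame, chain: str):
    """Collect N/CA/C/O per residue of the chain, in file order."""
    residues: dict[int, dict[str, np.ndarray]] = {}
    names: dict[int, str] = {}
    order: list[int] = []
    for site in frame.sites:
        if site.chain_id != chain or site.insertion_code != "":
            continue
        if site.residue_number not in residues:
            residues[site.residue_number] = {}
            names[site.residue_number] = site.residue_name
            order.append(site.residue_number)
        if site.atom_name in ("N", "CA", "C", "O", "H"):
            residues[site.residue_number][site.atom_name] = site.position
    return order, residues, names


def assign_secondary_structure(frame: Frame, chain: str | None = None
                               ) -> dict[int, str]:
    """Per-residue H/E/C labels from the Kabsch-Sander H-bond criterion.

    Amide hydrogens absent from the coordinates (the usual case for
    crystal structures) are constructed on the peptide plane, opposite the
    bisector of the C(i-1)->N and CA->N directions.  A backbone hydrogen
    bond is accepted when the Kabsch-Sander electrostatic energy drops
    below -0.5 kcal/mol.  Four-turn patterns give H; isolated and extended
    bridges give E; everything else, including residues with missing
    backbone atoms, degrades to C.
    """
    if chain is None:
        chain = frame.chains()[0]
    order, residues, names = _backbone_by_residue(frame, chain)
    n = len(order)
    labels = {r: "C" for r in order}
    if n == 0:
        return labels

    complete = [all(k in residues[r] for k in ("N", "CA", "C", "O")) for r in order]

    # Donor hydrogens: use the file's H if present, else build geometrically.
    h_pos: list[np.ndarray | None] = [None] * n
    for i, r in enumerate(order):
        res = residues[r]
        if names[r] == "PRO" or "N" not in res:
            continue
        if "H" in res:
            h_pos[i] = res["H"]
            continue
        if i == 0:
            continue
        prev = residues[order[i - 1]]
        if "C" not in prev or "CA" not in res:
            continue
        if np.linalg.norm(res["N"] - prev["C"]) > 2.5:   # chain break
            continue
        d1 = res["N"] - prev["C"]
        d2 = res["N"] - res["CA"]
        d = d1 / np.linalg.norm(d1) + d2 / np.linalg.norm(d2)
        h_pos[i] = res["N"] + 1.01 * d / np.linalg.norm(d)

    # hbond[a][d]: C=O of residue index a accepts the N-H of residue index d.
    hbond = np.zeros((n, n), dtype=bool)
    for a in range(n):
        if not complete[a]:
            continue
        c = residues[order[a]]["C"]
        o = residues[order[a]]["O"]
        for d in range(n):
            if abs(a - d) < 2 or h_pos[d] is None or not complete[d]:
                continue
            nn = residues[order[d]]["N"]
            hh = h_pos[d]
            r_on = np.linalg.norm(o - nn)
            r_ch = np.linalg.norm(c - hh)
            r_oh = np.linalg.norm(o - hh)
            r_cn = np.linalg.norm(c - nn)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue
            energy = _Q1Q2F * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if energy < _HB_CUTOFF:
                hbond[a, d] = True

    # Helices: 4-turn at i when CO(i) bonds HN(i+4); H for i..i+3 when two
    # consecutive turns exist (DSSP minimal-helix rule).
    turn4 = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        if hbond[i, i + 4]:
            turn4[i] = True
    is_h = np.zeros(n, dtype=bool)
    for i in range(1, n - 3):
        if turn4[i - 1] and turn4[i]:
            is_h[i:i + 4] = True

    # Bridges (parallel / antiparallel), |i-j| >= 3.
    is_e = np.zeros(n, dtype=bool)
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            parallel = ((hbond[i - 1, j] and hbond[j, i + 1])
                        or (hbond[j - 1, i] and hbond[i, j + 1]))
            antiparallel = ((hbond[i, j] and hbond[j, i])
                            or (hbond[i - 1, j + 1] and hbond[j - 1, i + 1]))
            if parallel or antiparallel:
                is_e[i] = True
                is_e[j] = True

    for i, r in enumerate(order):
        if not complete[i]:
            continue                       # stays C
        if is_h[i]:
            labels[r] = "H"
        elif is_e[i]:
            labels[r] = "E"
    return labels


# ---------------------------------------------------------------------------
# SS-blended Needleman-Wunsch with affine gaps (Gotoh)
# ---------------------------------------------------------------------------

@dataclass
class SequenceAlignment:
    """Global alignment as aligned index pairs (0-based positions)."""

    aligned_pairs: list[tuple[int, int]]
    score: float
    gap_count: int


def _position_score(a: str, b: str, ssa: str, ssb: str, ss_weight: float) -> float:
    try:
        sub = float(_BLOSUM62[a, b])
    except (KeyError, IndexError):
        sub = float(_BLOSUM62["X", "X"])
    return (1.0 - ss_weight) * sub + ss_weight * _SS_SCORE[(ssa, ssb)]


def align_with_ss(ref_seq: str, ref_ss: str, tgt_seq: str, tgt_ss: str,
                  ss_weight: float = 0.3, gap_open: float = 12.0,
                  gap_extend: float = 1.0) -> SequenceAlignment:
    """Global alignment maximising blended residue + SS similarity.

    The per-position score is ``(1-w)*BLOSUM62 + w*M_ss`` with the match
    matrix rewarding identical H/E/C labels.  Gaps are affine: the first
    gapped position costs ``gap_open``, each extension ``gap_extend``.
    Traceback ties break deterministically: match first, then a gap in the
    target, then a gap in the reference.
    """
    if not ref_seq or not tgt_seq:
        raise ValueError("sequences must be non-empty")
    if not 0.0 <= ss_weight <= 1.0:
        raise ValueError("ss_weight must lie in [0, 1]")
    if len(ref_seq) != len(ref_ss) or len(tgt_seq) != len(tgt_ss):
        raise ValueError("sequence and SS strings must have equal length")
    n, m = len(ref_seq), len(tgt_seq)
    neg = -np.inf
    # M: ref i aligned to tgt j; X: gap in target (ref consumed);
    # Y: gap in reference (tgt consumed).
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)
    Y = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _position_score(ref_seq[i - 1], tgt_seq[j - 1],
                                ref_ss[i - 1], tgt_ss[j - 1], ss_weight)
            M[i, j] = s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend,
                          Y[i - 1, j] - gap_open)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend,
                          X[i, j - 1] - gap_open)

    score = max(M[n, m], X[n, m], Y[n, m])
    # Traceback with the stated tie-breaking preference.
    pairs: list[tuple[int, int]] = []
    gap_count = 0
    i, j = n, m
    if M[n, m] >= score:
        state = "M"
    elif X[n, m] >= score:
        state = "X"
    else:
        state = "Y"
    tol = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            pairs.append((i - 1, j - 1))
            s = _position_score(ref_seq[i - 1], tgt_seq[j - 1],
                                ref_ss[i - 1], tgt_ss[j - 1], ss_weight)
            prev = M[i, j] - s
            if i == 1 and j == 1:
                state = "M"
            elif abs(M[i - 1, j - 1] - prev) < tol:
                state = "M"
            elif abs(X[i - 1, j - 1] - prev) < tol:
                state = "X"
            else:
                state = "Y"
            i -= 1
            j -= 1
        elif state == "X":
            gap_count += 1
            if i > 1 or j > 0:
                if abs(M[i - 1, j] - gap_open - X[i, j]) < tol:
                    state = "M"
                elif abs(X[i - 1, j] - gap_extend - X[i, j]) < tol:
                    state = "X"
                else:
                    state = "Y"
            i -= 1
        else:
            gap_count += 1
            if j > 1 or i > 0:
                if abs(M[i, j - 1] - gap_open - Y[i, j]) < tol:
                    state = "M"
                elif abs(Y[i, j - 1] - gap_extend - Y[i, j]) < tol:
                    state = "Y"
                else:
                    state = "X"
            j -= 1
        if i == 0 and j == 0:
            break
    pairs.reverse()
    return SequenceAlignment(pairs, float(score), gap_count)


# ---------------------------------------------------------------------------
# Kabsch least-squares fitting
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """x -> rotation @ x + translation, with the post-fit RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd_after_fit: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Optimal proper rotation + translation of ``mobile`` onto ``reference``.

    Uses the SVD form of the Kabsch solution with the determinant
    correction that excludes reflections.  Raises
    :class:`DegenerateGeometryError` for fewer than three points or
    collinear input.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 points")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    P = mobile - mc
    Q = reference - rc
    for mat in (P, Q):
        s = np.linalg.svd(mat, compute_uv=False)
        if s[1] < 1e-8 * max(1.0, s[0]):
            raise DegenerateGeometryError("points are (near-)collinear")
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    fitted = P @ R.T + rc
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return RigidTransform(R, t, rmsd)


def superpose_ensemble(ensemble: Ensemble, reference: Frame,
                       core: ResidueRangeSet,
                       atom_names: tuple[str, ...] = ("N", "CA", "C"),
                       chain: str | None = None,
                       reference_chain: str | None = None) -> Ensemble:
    """Fit every frame onto the reference over the rigid-core backbone.

    Each frame gets its own least-squares transform on the core backbone
    atoms; all other atoms ride along rigidly, so intra-frame geometry is
    preserved exactly.
    """
    ref_xyz = frame_coordinates(reference, core, atom_names, reference_chain)
    mob = select_coordinates(ensemble, core, atom_names, chain)
    fitted_frames = []
    for fi, frame in enumerate(ensemble.frames):
        tr = kabsch_fit(mob[fi], ref_xyz)
        fitted_frames.append(frame.transformed(tr.rotation, tr.translation))
    return Ensemble(fitted_frames, list(ensemble.topology_key), ensemble.source_label)


def rmsf(fitted: Ensemble, selection: ResidueRangeSet,
         atom_names: tuple[str, ...] = ("CA",),
         chain: str | None = None) -> dict[int, float]:
    """Per-residue RMSF (A) about the ensemble-mean position.

    With the default Calpha selection there is one atom per residue; for
    wider selections the per-residue value averages the atomic mean-square
    fluctuations before the square root.
    """
    if len(fitted.frames) < 2:
        raise ValueError("RMSF is undefined for a single frame")
    xyz = select_coordinates(fitted, selection, atom_names, chain)
    mean = xyz.mean(axis=0)
    msf = np.mean(np.sum((xyz - mean) ** 2, axis=2), axis=0)   # per atom
    if chain is None:
        chain = fitted.first_chain()
    keys = [(r, a) for r in selection.residues() for a in sorted(set(atom_names))]
    per_residue: dict[int, list[float]] = {}
    for (r, _a), value in zip(keys, msf):
        per_residue.setdefault(r, []).append(float(value))
    return {r: float(np.sqrt(np.mean(v))) for r, v in per_residue.items()}
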