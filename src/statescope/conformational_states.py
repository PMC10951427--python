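"""Essential-dynamics analysis and conformational-state classification.

The workflow mirrors how the SH2 conformational states are defined:

1. PCA of the superposed Calpha coordinates (residues 6-101 of the
   reference domain by default) gives the dominant collective mode ``v``.
2. Two *subvectors* are derived from ``v``: the trajectory is first
   filtered to contain only motion along ``v`` and PCA is then re-run on
   the atom subsets of the pY site (Ser34-Phe41) and of the +5 site
   (Gln57-Glu97).  Each subset's first mode, sign-calibrated so that a
   closed reference geometry projects positively, spans one axis of the
   *essential plane*.
3. Every structure is projected onto the plane and classified into one of
   four states: alpha (pY closed, +5 closed), beta (open, open), gamma
   (closed, open), delta (open, closed).

The module also provides extreme-projection endpoint reconstruction and
GROMOS-style neighbor-counting RMSD clustering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .ensemble_io import AtomSite, Ensemble, Frame, ResidueRangeSet

__all__ = [
    "PCAModel",
    "ModeSubvector",
    "PlaneProjection",
    "ClusterResult",
    "STATE_LABELS",
    "PY_SITE_RANGE",
    "PLUS5_SITE_RANGE",
    "PCA_RANGE",
    "fit_pca",
    "project",
    "extract_subvectors",
    "essential_plane",
    "classify_state",
    "extreme_projection_structures",
    "cluster_conformations",
]

STATE_LABELS = ("alpha", "beta", "gamma", "delta")

#: Default analysis ranges in reference (SHP2 N-SH2) author numbering.
PCA_RANGE = ResidueRangeSet([(6, 101)])
PY_SITE_RANGE = ResidueRangeSet([(34, 41)])      # Ser34-Phe41, the pY loop
PLUS5_SITE_RANGE = ResidueRangeSet([(57, 97)])   # Gln57-Glu97, the +5 site


@dataclass
class PCAModel:
    """Mean structure plus eigenmodes of the coordinate covariance.

    ``atom_keys`` fixes the flattened coordinate order: entry ``i`` of the
    mean corresponds to components ``3i..3i+2`` of each eigenvector.
    """

    mean_coordinates: np.ndarray                    # atoms x 3
    eigenvectors: np.ndarray                        # modes x 3*atoms, unit rows
    eigenvalues: np.ndarray                         # A^2, descending
    atom_keys: list[tuple[str, int, str, str]]      # (chain, resnum, resname, atom)

    @property
    def n_atoms(self) -> int:
        return self.mean_coordinates.shape[0]

    def atom_rows(self, selection: ResidueRangeSet) -> np.ndarray:
        """Row indices of atoms whose residue falls in the selection."""
        return np.array([i for i, (_c, r, _rn, _a) in enumerate(self.atom_keys)
                         if r in selection], dtype=int)

    def frame_coordinates(self, frame: Frame) -> np.ndarray:
        """Model-ordered atoms x 3 coordinates of a frame."""
        out = np.empty((self.n_atoms, 3))
        for i, (c, r, _rn, a) in enumerate(self.atom_keys):
            out[i] = frame.atom(c, r, a).position
        return out

    def reconstruct_frame(self, flat_coordinates: np.ndarray,
                          frame_index: int = 0) -> Frame:
        xyz = np.asarray(flat_coordinates, dtype=float).reshape(self.n_atoms, 3)
        sites = [AtomSite(c, r, rn, a, xyz[i])
                 for i, (c, r, rn, a) in enumerate(self.atom_keys)]
        return Frame(sites, frame_index)

    def save(self, path: str | Path) -> None:
        """Persist as NPZ with a JSON sidecar describing the atom order."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"),
                 mean_coordinates=self.mean_coordinates,
                 eigenvectors=self.eigenvectors,
                 eigenvalues=self.eigenvalues)
        sidecar = {"atom_keys": [list(k) for k in self.atom_keys]}
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "PCAModel":
        path = Path(path)
        data = np.load(path.with_suffix(".npz"))
        sidecar = json.loads(path.with_suffix(".json").read_text())
        keys = [(c, int(r), rn, a) for c, r, rn, a in sidecar["atom_keys"]]
        return cls(data["mean_coordinates"], data["eigenvectors"],
                   data["eigenvalues"], keys)


@dataclass
class ModeSubvector:
    """Unit restriction of a collective mode to a residue subset."""

    residue_subset: ResidueRangeSet
    components: np.ndarray          # 3 * len(atom_rows), unit norm
    atom_rows: np.ndarray           # rows of the parent model's atoms
    sign_calibration: int = 1
    parent_mode_index: int = 0

    def __post_init__(self) -> None:
        norm = np.linalg.norm(self.components)
        if abs(norm - 1.0) > 1e-10:
            raise ValueError("subvector components must be unit norm")


@dataclass
class PlaneProjection:
    p_py: float
    p_plus5: float
    frame_index: int = 0


@dataclass
class ClusterResult:
    assignments: dict[int, int]         # frame index -> cluster id
    centroids: list[int]                # frame index of each cluster centroid
    cutoff: float
    cumulative_fraction: list[float]    # over descending cluster sizes

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def _ensemble_matrix(fitted: Ensemble, selection: ResidueRangeSet,
                     atom_names: Iterable[str], chain: str | None):
    from .ensemble_io import select_coordinates
    if chain is None:
        chain = fitted.first_chain()
    xyz = select_coordinates(fitted, selection, atom_names, chain)
    names = sorted(set(atom_names))
    frame0 = fitted.frames[0]
    keys = []
    for r in selection.residues():
        for a in names:
            resname = frame0.atom(chain, r, a).residue_name
            keys.append((chain, r, resname, a))
    return xyz.reshape(len(fitted.frames), -1), keys


def fit_pca(fitted: Ensemble, selection: ResidueRangeSet = PCA_RANGE,
            atom_names: tuple[str, ...] = ("CA",),
            chain: str | None = None) -> PCAModel:
    """Eigendecompose the coordinate covariance of a superposed ensemble.

    The ensemble must already be superposed on the rigid core.  The
    covariance uses the population normalisation 1/F, so the eigenvalue
    sum equals the total coordinate variance about the mean.
    """
    if len(fitted.frames) < 2:
        raise ValueError("PCA needs at least 2 frames")
    X, keys = _ensemble_matrix(fitted, selection, atom_names, chain)
    mean = X.mean(axis=0)
    centered = X - mean
    # SVD route: eigenvalues of (1/F) X^T X without forming the 3N x 3N matrix.
    _u, s, vt = np.linalg.svd(centered / np.sqrt(len(X)), full_matrices=False)
    eigenvalues = s ** 2
    order = np.argsort(eigenvalues)[::-1]
    return PCAModel(mean.reshape(-1, 3), vt[order], eigenvalues[order], keys)


def project(frame_or_ensemble, model: PCAModel, mode_index: int = 0) -> np.ndarray | float:
    """Projection(s) onto one eigenvector: (x - mean) . v."""
    v = model.eigenvectors[mode_index]
    mean = model.mean_coordinates.ravel()
    if isinstance(frame_or_ensemble, Frame):
        x = model.frame_coordinates(frame_or_ensemble).ravel()
        return float((x - mean) @ v)
    return np.array([
        (model.frame_coordinates(f).ravel() - mean) @ v
        for f in frame_or_ensemble.frames
    ])


# ---------------------------------------------------------------------------
# Subvectors and the essential plane
# ---------------------------------------------------------------------------

def _subset_first_mode(filtered: np.ndarray, cols: np.ndarray) -> np.ndarray:
    sub = filtered[:, cols]
    sub = sub - sub.mean(axis=0)
    _u, s, vt = np.linalg.svd(sub / np.sqrt(len(sub)), full_matrices=False)
    return vt[np.argmax(s ** 2)]


def _subset_columns(rows: np.ndarray) -> np.ndarray:
    return np.concatenate([[3 * i, 3 * i + 1, 3 * i + 2] for i in rows])


def extract_subvectors(model: PCAModel, fitted: Ensemble,
                       py_range: ResidueRangeSet = PY_SITE_RANGE,
                       plus5_range: ResidueRangeSet = PLUS5_SITE_RANGE,
                       closed_reference: Frame | None = None,
                       mode_index: int = 0) -> tuple[ModeSubvector, ModeSubvector]:
    """Derive the pY-site and +5-site subvectors from mode ``v``.

    Following the filtered-trajectory construction: every frame is
    replaced by ``mean + p*v`` (its reconstruction along the chosen mode),
    and PCA restricted to each site's atoms is run on that filtered
    trajectory.  Each first mode is returned as a unit subvector.

    Sign calibration: if ``closed_reference`` is given (a frame in the
    closed geometry of both sites), each subvector's sign is flipped so
    that frame projects positively — positive projection then means
    "closed site".  Without a reference the sign is fixed by making the
    largest-magnitude component positive.
    """
    v = model.eigenvectors[mode_index]
    mean = model.mean_coordinates.ravel()
    p = project(fitted, model, mode_index)
    filtered = mean + np.outer(p, v)

    subvectors = []
    for rng in (py_range, plus5_range):
        rows = model.atom_rows(rng)
        if rows.size == 0:
            raise ValueError(f"no model atoms in residue range {rng.ranges}")
        cols = _subset_columns(rows)
        u = _subset_first_mode(filtered, cols)
        sign = 1
        if closed_reference is not None:
            x = model.frame_coordinates(closed_reference).ravel()
            if (x - mean)[cols] @ u < 0:
                sign = -1
        elif u[np.argmax(np.abs(u))] < 0:
            sign = -1
        subvectors.append(ModeSubvector(rng, sign * u, rows, sign, mode_index))
    return subvectors[0], subvectors[1]


def essential_plane(frames: Ensemble | Sequence[Frame] | Frame,
                    subvectors: tuple[ModeSubvector, ModeSubvector],
                    model: PCAModel) -> list[PlaneProjection]:
    """Project structures onto the (pY, +5) subvector plane."""
    if isinstance(frames, Frame):
        frame_list: Sequence[Frame] = [frames]
    elif isinstance(frames, Ensemble):
        frame_list = frames.frames
    else:
        frame_list = frames
    mean = model.mean_coordinates.ravel()
    py, p5 = subvectors
    cols_py = _subset_columns(py.atom_rows)
    cols_p5 = _subset_columns(p5.atom_rows)
    out = []
    for frame in frame_list:
        dx = model.frame_coordinates(frame).ravel() - mean
        out.append(PlaneProjection(float(dx[cols_py] @ py.components),
                                   float(dx[cols_p5] @ p5.components),
                                   frame.frame_index))
    return out


def classify_state(p: PlaneProjection,
                   boundaries: tuple[float, float] = (0.0, 0.0)) -> str:
    """Assign the quadrant state of one plane projection.

    Positive (calibrated) projection means a closed site; projections
    exactly on a boundary count as closed.  alpha = closed/closed,
    beta = open/open, gamma = pY closed / +5 open, delta = pY open /
    +5 closed.
    """
    b_py, b_p5 = boundaries
    if not (np.isfinite(b_py) and np.isfinite(b_p5)):
        raise ValueError("boundaries must be finite")
    closed_py = p.p_py >= b_py
    closed_p5 = p.p_plus5 >= b_p5
    if closed_py and closed_p5:
        return "alpha"
    if not closed_py and not closed_p5:
        return "beta"
    if closed_py:
        return "gamma"
    return "delta"


def extreme_projection_structures(model: PCAModel, fitted: Ensemble,
                                  mode_index: int = 0) -> tuple[Frame, Frame]:
    """Endpoint reconstructions mean +/- p_max * v of the chosen mode."""
    if len(fitted.frames) < 2:
        raise ValueError("need at least 2 frames")
    p = project(fitted, model, mode_index)
    p_max = float(np.max(np.abs(p)))
    v = model.eigenvectors[mode_index]
    mean = model.mean_coordinates.ravel()
    plus = model.reconstruct_frame(mean + p_max * v, 0)
    minus = model.reconstruct_frame(mean - p_max * v, 1)
    return plus, minus


# ---------------------------------------------------------------------------
# GROMOS-style neighbor-counting clustering
# ---------------------------------------------------------------------------

def cluster_conformations(fitted: Ensemble, selection: ResidueRangeSet,
                          cutoff: float = 1.0,
                          atom_names: tuple[str, ...] = ("CA",),
                          chain: str | None = None) -> ClusterResult:
    """Neighbor-counting clustering at an RMSD cutoff (A).

    The frame with the most neighbors within ``cutoff`` becomes the first
    centroid and its neighborhood the first cluster; the procedure repeats
    on the remainder.  Ties break to the lowest frame index.  RMSDs are
    computed on the already-superposed coordinates (no per-pair refit).
    The default 1 A Calpha cutoff corresponds to the usual 0.1 nm choice.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    from .ensemble_io import select_coordinates
    xyz = select_coordinates(fitted, selection, atom_names, chain)
    n = xyz.shape[0]
    flat = xyz.reshape(n, -1)
    natoms = xyz.shape[1]
    d2 = np.sum((flat[:, None, :] - flat[None, :, :]) ** 2, axis=2) / natoms
    neighbors = np.sqrt(d2) <= cutoff

    remaining = np.ones(n, dtype=bool)
    assignments: dict[int, int] = {}
    centroids: list[int] = []
    sizes: list[int] = []
    cluster_id = 0
    while remaining.any():
        counts = (neighbors & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))        # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbors[center] & remaining)
        for m in members:
            assignments[int(m)] = cluster_id
        centroids.append(center)
        sizes.append(len(members))
        remaining[members] = False
        cluster_id += 1

    frac = np.cumsum(sorted(sizes, reverse=True)) / n
    return ClusterResult(assignments, centroids, float(cutoff),
                         [float(f) for f in frac])
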