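"""Batch census of SH2-domain structures against a reference domain.

Each candidate structure is screened as one survey entry: its
best-aligning chain is found with the secondary-structure-weighted
sequence alignment, residues are mapped onto the reference numbering,
and entries whose mapped pY loop does not have exactly the reference
loop length (eight residues) or whose descriptor backbone atoms are not
fully resolved are excluded with an explicit reason.  Included entries
contribute one observation per model: the projection onto the pY-site
subvector and the beta-sheet spread distance, later stratified by
experimental method (X-ray vs NMR).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .conformational_states import ModeSubvector, PCAModel
from .descriptors import KEY_DISTANCE_ATOMS
from .ensemble_io import (
    Ensemble,
    Frame,
    ResidueRangeSet,
    write_table,
)
from .superposition import (
    DegenerateGeometryError,
    align_with_ss,
    assign_secondary_structure,
    kabsch_fit,
)

__all__ = [
    "SurveyReference",
    "SurveyEntry",
    "make_survey_reference",
    "screen_entry",
    "stratify_by_method",
    "survey_report",
]

EXCLUSION_REASONS = ("py_loop_length", "incomplete_backbone", "no_alignable_chain")


@dataclass
class SurveyReference:
    """Reference domain bundle used to screen every survey entry."""

    frame: Frame
    chain: str
    sequence: str
    numbering: list[int]
    ss: str
    model: PCAModel
    py_subvector: ModeSubvector
    core: ResidueRangeSet
    py_loop_range: ResidueRangeSet
    spread_pair: tuple[tuple[int, str], tuple[int, str]]


@dataclass
class SurveyEntry:
    pdb_id: str
    assembly_id: int = 1
    method: str = "other"
    model_count: int = 0
    included: bool = False
    exclusion_reason: str | None = None
    projections: list[float] = field(default_factory=list)
    sheet_spread: list[float] = field(default_factory=list)
    best_chain: str | None = None
    alignment_score: float = float("nan")

    def __post_init__(self) -> None:
        if not self.included and self.exclusion_reason is None and self.model_count:
            raise ValueError("excluded entries need a reason")


def make_survey_reference(frame: Frame, model: PCAModel,
                          py_subvector: ModeSubvector, core: ResidueRangeSet,
                          py_loop_range: ResidueRangeSet | None = None,
                          spread_pair=None, chain: str | None = None
                          ) -> SurveyReference:
    """Bundle the reference frame, its sequence/SS and the pY-site mode."""
    if chain is None:
        chain = frame.chains()[0]
    ens = Ensemble([frame.copy()])
    from .ensemble_io import extract_sequence
    sequence, numbering = extract_sequence(ens, chain)
    labels = assign_secondary_structure(frame, chain)
    ss = "".join(labels.get(r, "C") for r in numbering)
    if py_loop_range is None:
        py_loop_range = ResidueRangeSet([(34, 41)])
    if spread_pair is None:
        spread_pair = KEY_DISTANCE_ATOMS["beta_sheet_spread"]
    return SurveyReference(frame, chain, sequence, numbering, ss, model,
                           py_subvector, core, py_loop_range, spread_pair)


def _best_chain_alignment(ensemble: Ensemble, reference: SurveyReference,
                          alignment_params: dict):
    from .ensemble_io import extract_sequence
    frame0 = ensemble.frames[0]
    best = None
    for chain in frame0.chains():
        try:
            seq, numbering = extract_sequence(ensemble, chain)
            labels = assign_secondary_structure(frame0, chain)
            ss = "".join(labels.get(r, "C") for r in numbering)
            aln = align_with_ss(reference.sequence, reference.ss, seq, ss,
                                **alignment_params)
        except (ValueError, KeyError):
            continue
        if best is None or aln.score > best[1].score:
            best = (chain, aln, numbering)
    return best


def screen_entry(ensemble: Ensemble, reference: SurveyReference,
                 pdb_id: str = "", assembly_id: int = 1,
                 method: str | None = None,
                 alignment_params: dict | None = None) -> SurveyEntry:
    """Screen one structure (all its models) against the reference.

    The best-aligning chain is chosen by alignment score; residues are
    mapped onto the reference numbering through the aligned pairs.  The
    entry is excluded when the mapped pY loop is not exactly the
    reference length (``py_loop_length``) or when a mapped descriptor
    backbone atom is missing in any model (``incomplete_backbone``).
    Otherwise each model yields a pY projection (after a least-squares
    fit of the mapped core Calpha atoms onto the reference) and a
    beta-sheet spread distance.
    """
    if method is None:
        method = getattr(ensemble, "method", "other")
    params = alignment_params or {}
    n_models = len(ensemble.frames)

    best = _best_chain_alignment(ensemble, reference, params)
    if best is None:
        return SurveyEntry(pdb_id, assembly_id, method, n_models, False,
                           "no_alignable_chain")
    chain, aln, tgt_numbering = best

    # reference residue number -> target residue number
    mapping: dict[int, int] = {}
    loop_positions: list[int] = []   # target indices aligned to the loop
    for k, (ri, ti) in enumerate(aln.aligned_pairs):
        ref_num = reference.numbering[ri]
        mapping[ref_num] = tgt_numbering[ti]
        if ref_num in reference.py_loop_range:
            loop_positions.append(ti)

    loop_residues = reference.py_loop_range.residues()
    loop_ok = (len(loop_positions) == len(loop_residues)
               and all(b == a + 1 for a, b in zip(loop_positions, loop_positions[1:])))
    if not loop_ok:
        return SurveyEntry(pdb_id, assembly_id, method, n_models, False,
                           "py_loop_length", best_chain=chain,
                           alignment_score=aln.score)

    # atoms required in every model
    sub_rows = reference.py_subvector.atom_rows
    sub_keys = [reference.model.atom_keys[i] for i in sub_rows]
    required: list[tuple[int, str]] = []
    for (_c, ref_res, _rn, atom) in sub_keys:
        if ref_res not in mapping:
            return SurveyEntry(pdb_id, assembly_id, method, n_models, False,
                               "incomplete_backbone", best_chain=chain,
                               alignment_score=aln.score)
        required.append((mapping[ref_res], atom))
    (s_r1, s_a1), (s_r2, s_a2) = reference.spread_pair
    for ref_res, atom in ((s_r1, s_a1), (s_r2, s_a2)):
        if ref_res not in mapping:
            return SurveyEntry(pdb_id, assembly_id, method, n_models, False,
                               "incomplete_backbone", best_chain=chain,
                               alignment_score=aln.score)
        required.append((mapping[ref_res], atom))
    core_pairs = [(r, mapping[r]) for r in reference.core.residues() if r in mapping]
    required.extend((t, "CA") for _r, t in core_pairs)
    for frame in ensemble.frames:
        for res, atom in required:
            if not frame.has_atom(chain, res, atom):
                return SurveyEntry(pdb_id, assembly_id, method, n_models, False,
                                   "incomplete_backbone", best_chain=chain,
                                   alignment_score=aln.score)
    if len(core_pairs) < 3:
        return SurveyEntry(pdb_id, assembly_id, method, n_models, False,
                           "no_alignable_chain", best_chain=chain,
                           alignment_score=aln.score)

    ref_core_xyz = np.array([
        reference.frame.atom(reference.chain, r, "CA").position
        for r, _t in core_pairs
    ])
    # projection origin: the reference domain itself, so a rigid copy of the
    # reference projects to exactly zero
    ref_sub_flat = np.array([
        reference.frame.atom(reference.chain, k[1], k[3]).position
        for k in sub_keys
    ]).ravel()
    projections: list[float] = []
    spreads: list[float] = []
    for frame in ensemble.frames:
        tgt_core = np.array([frame.atom(chain, t, "CA").position
                             for _r, t in core_pairs])
        try:
            tr = kabsch_fit(tgt_core, ref_core_xyz)
        except DegenerateGeometryError:
            return SurveyEntry(pdb_id, assembly_id, method, n_models, False,
                               "no_alignable_chain", best_chain=chain,
                               alignment_score=aln.score)
        sub_xyz = np.array([
            tr.apply(frame.atom(chain, t, a).position[None, :])[0]
            for t, a in ((mapping[k[1]], k[3]) for k in sub_keys)
        ])
        dx = sub_xyz.ravel() - ref_sub_flat
        projections.append(float(dx @ reference.py_subvector.components))
        p1 = frame.atom(chain, mapping[s_r1], s_a1).position
        p2 = frame.atom(chain, mapping[s_r2], s_a2).position
        spreads.append(float(np.linalg.norm(p1 - p2)))

    return SurveyEntry(pdb_id, assembly_id, method, n_models, True, None,
                       projections, spreads, chain, aln.score)


def stratify_by_method(entries: list[SurveyEntry], bins: int = 40,
                       projection_range: tuple[float, float] | None = None,
                       spread_range: tuple[float, float] | None = None) -> dict:
    """Pool per-model observations within each method and histogram them.

    Every model of every included entry contributes one observation, so
    a 20-model NMR entry adds 20 points to the NMR stratum.  Histograms
    are normalised to unit mass per method.
    """
    included = [e for e in entries if e.included]
    if not included:
        raise ValueError("no included entries to stratify")
    out: dict[str, dict] = {}
    all_proj = np.concatenate([e.projections for e in included])
    all_spread = np.concatenate([e.sheet_spread for e in included])
    pr = projection_range or (float(all_proj.min()), float(all_proj.max()) + 1e-9)
    sr = spread_range or (float(all_spread.min()), float(all_spread.max()) + 1e-9)
    for method in sorted({e.method for e in included}):
        proj = np.concatenate([e.projections for e in included if e.method == method])
        spread = np.concatenate([e.sheet_spread for e in included if e.method == method])
        hp, ep = np.histogram(proj, bins=bins, range=pr)
        hs, es = np.histogram(spread, bins=bins, range=sr)
        out[method] = {
            "projections": proj,
            "sheet_spread": spread,
            "projection_hist": (hp / hp.sum(), ep),
            "spread_hist": (hs / hs.sum(), es),
        }
    return out


def survey_report(entries: list[SurveyEntry], path: str | Path | None = None
                  ) -> dict:
    """Inclusion/exclusion accounting plus an optional TSV dump.

    The counts satisfy total = included + sum over exclusion reasons,
    and the conformation count sums the model counts of included
    entries (every model is one analysed conformation).
    """
    counts = {
        "total": len(entries),
        "included": sum(e.included for e in entries),
        "conformations": sum(e.model_count for e in entries if e.included),
    }
    for reason in EXCLUSION_REASONS:
        counts[f"excluded_{reason}"] = sum(
            1 for e in entries if not e.included and e.exclusion_reason == reason)
    if path is not None:
        rows = [{
            "pdb_id": e.pdb_id,
            "assembly_id": e.assembly_id,
            "method": e.method,
            "model_count": e.model_count,
            "included": e.included,
            "exclusion_reason": e.exclusion_reason or "",
            "mean_projection": float(np.mean(e.projections)) if e.projections else np.nan,
            "mean_sheet_spread": float(np.mean(e.sheet_spread)) if e.sheet_spread else np.nan,
        } for e in entries]
        write_table(rows, path)
    return counts
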