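"""Diagnostic interatomic distances of the SH2 conformational transition.

Four distances summarise the functional geometry of an SH2 domain (author
numbering of the SHP2 N-SH2 domain):

* pY loop opening      Lys35 CA - Thr42 CA   (~9 A closed, ~11 A open)
* beta-sheet spread    Gly39 C  - Asn58 N    (~4 A zipped, ~12 A unzipped)
* binding-cleft opening Gly67 CA - Lys89 CA  (~5 A inaccessible, ~14 A wide)
* +5 site opening      Tyr66 CA - Leu88 CA   (~7 A closed, ~12 A open)
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np

from .ensemble_io import Ensemble, Frame

__all__ = ["DistanceSet", "KEY_DISTANCE_ATOMS", "key_distances",
           "distance_series", "bivariate_histogram"]

#: field name -> ((residue, atom), (residue, atom)) in reference numbering.
KEY_DISTANCE_ATOMS = {
    "py_loop_opening": ((35, "CA"), (42, "CA")),
    "beta_sheet_spread": ((39, "C"), (58, "N")),
    "cleft_opening": ((67, "CA"), (89, "CA")),
    "plus5_opening": ((66, "CA"), (88, "CA")),
}


@dataclass
class DistanceSet:
    py_loop_opening: float
    beta_sheet_spread: float
    cleft_opening: float
    plus5_opening: float
    frame_index: int = 0

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            if f.name == "frame_index":
                continue
            v = getattr(self, f.name)
            if not 0.0 < v < 100.0:
                raise ValueError(f"{f.name} = {v} A outside the sane (0, 100) range")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def key_distances(frame: Frame, chain: str | None = None,
                  numbering_offset: int = 0) -> DistanceSet:
    """Compute the four diagnostic distances for one frame.

    ``numbering_offset`` is added to the reference residue numbers before
    lookup, for chains numbered differently from the reference domain.
    """
    if chain is None:
        chain = frame.chains()[0]
    values = {}
    for name, ((r1, a1), (r2, a2)) in KEY_DISTANCE_ATOMS.items():
        p1 = frame.atom(chain, r1 + numbering_offset, a1).position
        p2 = frame.atom(chain, r2 + numbering_offset, a2).position
        values[name] = float(np.linalg.norm(p1 - p2))
    return DistanceSet(**values, frame_index=frame.frame_index)


def distance_series(ensemble: Ensemble, chain: str | None = None,
                    numbering_offset: int = 0) -> list[DistanceSet]:
    """One :class:`DistanceSet` per frame, frame order preserved."""
    return [key_distances(f, chain, numbering_offset) for f in ensemble.frames]


def bivariate_histogram(series: list[DistanceSet],
                        fields: tuple[str, str] = ("beta_sheet_spread", "plus5_opening"),
                        bins: int | tuple[int, int] = 52,
                        range: tuple[tuple[float, float], tuple[float, float]] =
                        ((3.0, 16.0), (3.0, 16.0))):
    """Joint density over two distance fields plus its two marginals.

    The default grid covers 3-16 A in 0.25-A bins, spanning the zipped to
    fully unzipped regime.  The joint is normalised to total mass 1; the
    marginals are the row/column sums of the joint.

    Returns ``(joint, x_edges, y_edges, marginal_x, marginal_y)``.
    """
    if not series:
        raise ValueError("empty distance series")
    x = np.array([getattr(d, fields[0]) for d in series])
    y = np.array([getattr(d, fields[1]) for d in series])
    joint, xe, ye = np.histogram2d(x, y, bins=bins, range=range)
    total = joint.sum()
    if total > 0:
        joint = joint / total
    return joint, xe, ye, joint.sum(axis=1), joint.sum(axis=0)
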