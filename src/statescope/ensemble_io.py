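"""Coordinate-ensemble I/O and atom selection.

Reads multi-model PDB files into a lightweight :class:`Ensemble` container
(one :class:`Frame` per MODEL record), provides deterministic coordinate
selection by residue range and atom name, sequence extraction, and TSV
table round-tripping.  All downstream stages (superposition, descriptors,
PCA, survey, RDC fitting) consume these containers.

Parsing and writing of the PDB format are delegated to :mod:`gemmi`;
this module only defines the in-memory contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger("statescope")

__all__ = [
    "AtomSite",
    "Frame",
    "Ensemble",
    "ResidueRangeSet",
    "EmptyEnsembleError",
    "MissingAtomError",
    "read_ensemble",
    "write_ensemble",
    "select_coordinates",
    "frame_coordinates",
    "extract_sequence",
    "write_table",
    "read_table",
]

# Standard 3->1 letter mapping; anything else (PTR, MSE, ligands...) maps to X.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class EmptyEnsembleError(ValueError):
    """No atoms survived filtering, or the file holds no models."""


class MissingAtomError(KeyError):
    """A requested (residue, atom) pair is absent from the topology."""


@dataclass
class AtomSite:
    """One atom record (author numbering, altloc-filtered upstream)."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    position: np.ndarray
    insertion_code: str = ""
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)) or self.position.shape != (3,):
            raise ValueError("AtomSite position must be a finite 3-vector")
        if not self.atom_name:
            raise ValueError("AtomSite atom_name must be non-empty")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.residue_number, self.insertion_code, self.atom_name)


@dataclass
class Frame:
    """One model/configuration: an ordered list of atom sites."""

    sites: list[AtomSite]
    frame_index: int = 0

    def __post_init__(self) -> None:
        self._index: dict[tuple[str, int, str, str], AtomSite] = {}
        for site in self.sites:
            if site.key in self._index:
                raise ValueError(f"duplicate atom {site.key} in frame {self.frame_index}")
            self._index[site.key] = site

    def atom(self, chain_id: str, residue_number: int, atom_name: str,
             insertion_code: str = "") -> AtomSite:
        try:
            return self._index[(chain_id, residue_number, insertion_code, atom_name)]
        except KeyError:
            raise MissingAtomError(
                f"atom {atom_name} of residue {residue_number}{insertion_code} "
                f"(chain {chain_id!r}) not found"
            ) from None

    def has_atom(self, chain_id: str, residue_number: int, atom_name: str,
                 insertion_code: str = "") -> bool:
        return (chain_id, residue_number, insertion_code, atom_name) in self._index

    def chains(self) -> list[str]:
        seen: list[str] = []
        for site in self.sites:
            if site.chain_id not in seen:
                seen.append(site.chain_id)
        return seen

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Frame":
        """Return a rigidly transformed copy (x -> R x + t)."""
        new_sites = [
            AtomSite(s.chain_id, s.residue_number, s.residue_name, s.atom_name,
                     rotation @ s.position + translation, s.insertion_code, s.altloc)
            for s in self.sites
        ]
        return Frame(new_sites, self.frame_index)

    def copy(self) -> "Frame":
        return self.transformed(np.eye(3), np.zeros(3))


@dataclass
class Ensemble:
    """Ordered frames sharing one topology.

    ``topology_key`` lists the (chain, residue_number, atom_name) triplets
    common to every frame, in ascending order.
    """

    frames: list[Frame]
    topology_key: list[tuple[str, int, str]] = field(default_factory=list)
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.frames:
            raise EmptyEnsembleError("an Ensemble needs at least one frame")
        if not self.topology_key:
            self.topology_key = _common_topology(self.frames)

    def __len__(self) -> int:
        return len(self.frames)

    def chains(self) -> list[str]:
        return self.frames[0].chains()

    def first_chain(self) -> str:
        return self.chains()[0]

    def subset(self, indices: Sequence[int]) -> "Ensemble":
        frames = [self.frames[i] for i in indices]
        return Ensemble(frames, list(self.topology_key), self.source_label)


def _common_topology(frames: Sequence[Frame]) -> list[tuple[str, int, str]]:
    common: set[tuple[str, int, str]] | None = None
    for frame in frames:
        keys = {(s.chain_id, s.residue_number, s.atom_name)
                for s in frame.sites if s.insertion_code == ""}
        common = keys if common is None else common & keys
    return sorted(common or set())


@dataclass(frozen=True)
class ResidueRangeSet:
    """Inclusive author-numbered residue ranges, non-overlapping."""

    ranges: tuple[tuple[int, int], ...]

    def __init__(self, ranges: Iterable[tuple[int, int]]):
        rs = tuple((int(a), int(b)) for a, b in ranges)
        for a, b in rs:
            if a > b:
                raise ValueError(f"range first {a} > last {b}")
        for (a1, b1), (a2, b2) in zip(sorted(rs), sorted(rs)[1:]):
            if a2 <= b1:
                raise ValueError("residue ranges overlap")
        object.__setattr__(self, "ranges", rs)

    @classmethod
    def from_string(cls, text: str) -> "ResidueRangeSet":
        """Parse e.g. ``"7-33,40-47,55"``."""
        ranges = []
        for part in text.split(","):
            part = part.strip()
            if "-" in part[1:]:
                head, tail = part.rsplit("-", 1)
                ranges.append((int(head), int(tail)))
            else:
                ranges.append((int(part), int(part)))
        return cls(ranges)

    def residues(self) -> list[int]:
        out: list[int] = []
        for a, b in sorted(self.ranges):
            out.extend(range(a, b + 1))
        return out

    def __contains__(self, residue_number: int) -> bool:
        return any(a <= residue_number <= b for a, b in self.ranges)


# ---------------------------------------------------------------------------
# PDB reading / writing (via gemmi)
# ---------------------------------------------------------------------------

def _method_from_structure(structure: gemmi.Structure) -> str:
    try:
        expdta = (structure.info["_exptl.method"] or "").upper()
    except KeyError:
        expdta = ""
    if "NMR" in expdta:
        return "nmr"
    if "X-RAY" in expdta or "DIFFRACTION" in expdta:
        return "xray"
    return "other"


def read_ensemble(path: str | Path, model_policy: str = "all") -> Ensemble:
    """Read a PDB file into an :class:`Ensemble`, one frame per MODEL.

    Altloc handling keeps blank or 'A' conformers only, so every atom key
    is unique and geometry is single-conformer.  Water molecules are
    dropped.  ``model_policy`` is ``"all"`` or ``"first"``.
    """
    if model_policy not in ("all", "first"):
        raise ValueError("model_policy must be 'all' or 'first'")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    structure = gemmi.read_pdb(str(path))
    frames: list[Frame] = []
    for mi, model in enumerate(structure):
        sites: list[AtomSite] = []
        for chain in model:
            for residue in chain:
                if residue.name in ("HOH", "WAT", "DOD"):
                    continue
                seen_names: set[str] = set()
                for atom in residue:
                    if atom.altloc not in ("", "A", "\x00"):
                        continue
                    if atom.name in seen_names:
                        continue
                    seen_names.add(atom.name)
                    pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    sites.append(AtomSite(
                        chain_id=chain.name,
                        residue_number=residue.seqid.num,
                        residue_name=residue.name,
                        atom_name=atom.name,
                        position=pos,
                        insertion_code=(residue.seqid.icode or "").strip(),
                        altloc="" if atom.altloc in ("", "\x00") else atom.altloc,
                    ))
        if sites:
            frames.append(Frame(sites, frame_index=mi))
        if model_policy == "first" and frames:
            break
    if not frames:
        raise EmptyEnsembleError(f"no atoms left after filtering in {path}")
    ens = Ensemble(frames, source_label=str(path))
    ens.method = _method_from_structure(structure)  # type: ignore[attr-defined]
    return ens


def write_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write frames as a multi-MODEL PDB file."""
    structure = gemmi.Structure()
    structure.name = ensemble.source_label or "statescope"
    for mi, frame in enumerate(ensemble.frames):
        model = gemmi.Model(str(mi + 1))
        chain_map: dict[str, gemmi.Chain] = {}
        res_map: dict[tuple[str, int, str], gemmi.Residue] = {}
        for site in frame.sites:
            chain = chain_map.get(site.chain_id)
            if chain is None:
                chain = gemmi.Chain(site.chain_id)
                chain_map[site.chain_id] = chain
            rkey = (site.chain_id, site.residue_number, site.insertion_code)
            residue = res_map.get(rkey)
            if residue is None:
                residue = gemmi.Residue()
                residue.name = site.residue_name
                residue.seqid = gemmi.SeqId(site.residue_number, site.insertion_code or " ")
                res_map[rkey] = residue
            atom = gemmi.Atom()
            atom.name = site.atom_name
            atom.pos = gemmi.Position(*site.position)
            atom.element = gemmi.Element(site.atom_name[0])
            residue.add_atom(atom)
        for rkey, residue in res_map.items():
            chain_map[rkey[0]].add_residue(residue)
        for chain in chain_map.values():
            model.add_chain(chain)
        structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def _selection_keys(ensemble: Ensemble, selection: ResidueRangeSet,
                    atom_names: Iterable[str], chain: str | None) -> list[tuple[str, int, str]]:
    if chain is None:
        chain = ensemble.first_chain()
    present = {(c, r, a) for (c, r, a) in ensemble.topology_key if c == chain}
    if not present:
        raise MissingAtomError(f"chain {chain!r} not present in topology")
    names = sorted(set(atom_names))
    keys: list[tuple[str, int, str]] = []
    for residue_number in selection.residues():
        for atom_name in names:
            key = (chain, residue_number, atom_name)
            if key not in present:
                raise MissingAtomError(
                    f"atom {atom_name} of residue {residue_number} (chain {chain!r}) "
                    "missing from the shared topology"
                )
            keys.append(key)
    return keys


def select_coordinates(ensemble: Ensemble, selection: ResidueRangeSet,
                       atom_names: Iterable[str], chain: str | None = None) -> np.ndarray:
    """Return a frames x atoms x 3 array for the selection.

    Atom order is deterministic: ascending residue number, then atom name,
    within the requested chain (default: first chain).  Raises
    :class:`MissingAtomError` naming the first absent (residue, atom).
    """
    keys = _selection_keys(ensemble, selection, atom_names, chain)
    out = np.empty((len(ensemble.frames), len(keys), 3))
    for fi, frame in enumerate(ensemble.frames):
        for ai, (c, r, a) in enumerate(keys):
            out[fi, ai] = frame.atom(c, r, a).position
    return out


def frame_coordinates(frame: Frame, selection: ResidueRangeSet,
                      atom_names: Iterable[str], chain: str | None = None) -> np.ndarray:
    """Atoms x 3 coordinates of one frame, same ordering as select_coordinates."""
    ens = Ensemble([frame.copy()])
    return select_coordinates(ens, selection, atom_names, chain)[0]


def extract_sequence(ensemble: Ensemble, chain: str | None = None
                     ) -> tuple[str, list[int]]:
    """One-letter sequence and per-residue author numbering, in file order.

    Nonstandard residues (phosphotyrosine PTR, selenomethionine MSE, ...)
    map to ``X``.
    """
    if chain is None:
        chain = ensemble.first_chain()
    frame = ensemble.frames[0]
    if chain not in frame.chains():
        raise KeyError(f"chain {chain!r} not present")
    letters: list[str] = []
    numbering: list[int] = []
    seen: set[tuple[int, str]] = set()
    for site in frame.sites:
        if site.chain_id != chain:
            continue
        rkey = (site.residue_number, site.insertion_code)
        if rkey in seen:
            continue
        seen.add(rkey)
        letters.append(THREE_TO_ONE.get(site.residue_name, "X"))
        numbering.append(site.residue_number)
    return "".join(letters), numbering


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_table(records: Sequence[dict], path: str | Path,
                columns: Sequence[str] | None = None) -> None:
    """Write keyed rows as a UTF-8 TSV with a header; floats at 4 decimals."""
    if records:
        keysets = {frozenset(r.keys()) for r in records}
        if len(keysets) != 1:
            raise ValueError("all rows must share one key set")
        df = pd.DataFrame(list(records))
        if columns is not None:
            df = df[list(columns)]
    else:
        df = pd.DataFrame(columns=list(columns or []))
    df.to_csv(path, sep="\t", index=False, float_format="%.4f", encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", encoding="utf-8")
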