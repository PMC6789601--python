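"""Coordinate-file ingestion and near-duplicate chain removal.

Reads PDB or mmCIF files into a minimal hierarchy (Structure > Chain >
Residue > Atom) keeping only polymer amino-acid residues, and removes
near-identical chain copies (non-crystallographic symmetry) by a global
sequence-identity filter before feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from Bio import Align

from .chemistry import STANDARD_AA, THREE_TO_ONE

__all__ = [
    "Atom", "Residue", "Chain", "Structure",
    "ParseError", "parse_structure", "sequence_identity", "deduplicate_chains",
]


class ParseError(ValueError):
    """Raised when a coordinate file cannot be read."""


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")


@dataclass
class Residue:
    """One residue: three-letter code, author index (+ insertion code), atoms by name."""

    type3: str
    index: int
    icode: str = ""
    atoms: dict[str, Atom] = field(default_factory=dict)

    @property
    def is_standard(self) -> bool:
        return self.type3 in STANDARD_AA

    @property
    def label(self) -> str:
        return f"{self.index}{self.icode}".strip()

    def get(self, name: str) -> Atom | None:
        return self.atoms.get(name)

    def position(self, name: str) -> np.ndarray | None:
        a = self.atoms.get(name)
        return None if a is None else a.position


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        """One-letter sequence over the standard residues, in file order."""
        return "".join(
            THREE_TO_ONE[r.type3] for r in self.residues if r.is_standard
        )


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)
    source_path: str = ""

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        available = ", ".join(c.id for c in self.chains) or "(none)"
        raise KeyError(f"chain {chain_id!r} not found; available: {available}")


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties resolved by file order
    best = atoms[0]
    for a in atoms[1:]:
        if a.occ > best.occ:
            best = a
    return best


def parse_structure(path: str | Path, model_index: int = 0) -> Structure:
    """Parse a PDB or mmCIF file into a Structure.

    Keeps only polymer amino-acid residues of the selected model; waters,
    ligands and nucleic acids are dropped. For alternate locations the
    highest-occupancy conformer is kept (ties: first in file).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), merge_chain_parts=True)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: file contains no models")
    if not 0 <= model_index < len(st):
        raise IndexError(
            f"model_index {model_index} out of range (file has {len(st)} model(s))"
        )
    model = st[model_index]

    out = Structure(id=st.name or path.stem, source_path=str(path))
    for gchain in model:
        chain = Chain(id=gchain.name)
        for gres in gchain:
            info = gemmi.find_tabulated_residue(gres.name)
            if info is None or not info.is_amino_acid() or info.is_water():
                continue
            res = Residue(type3=gres.name.upper(), index=gres.seqid.num,
                          icode=(gres.seqid.icode or "").strip())
            by_name: dict[str, list[gemmi.Atom]] = {}
            for ga in gres:
                by_name.setdefault(ga.name, []).append(ga)
            for name, group in by_name.items():
                ga = _pick_altloc(group)
                res.atoms[name] = Atom(
                    name=name,
                    element=ga.element.name,
                    position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    altloc=(ga.altloc or "").strip(),
                    occupancy=ga.occ,
                )
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            out.chains.append(chain)
    return out


def _aligner(match: float = 1.0, mismatch: float = 0.0,
             gap_open: float = -0.5, gap_extend: float = -0.1) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment percent identity between two one-letter sequences.

    Needleman-Wunsch with match=1, mismatch=0 and a small affine gap penalty;
    identity = identical aligned positions / alignment length (gaps included).
    Symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("sequence_identity requires non-empty sequences")
    if a == b:
        return 1.0
    alignment = _aligner().align(a, b)[0]
    identities = alignment.counts().identities
    return identities / alignment.length


def deduplicate_chains(structure: Structure, threshold: float = 0.95) -> list[Chain]:
    """Drop chains nearly identical to an earlier chain (NCS copies).

    Chains are scanned in file order; a chain is dropped when its global
    sequence identity to any previously kept chain is >= ``threshold``.
    Chains with no standard residues are kept untouched (nothing to align).
    """
    if not structure.chains:
        raise ValueError("structure has no chains")
    kept: list[Chain] = []
    for chain in structure.chains:
        seq = chain.sequence
        duplicate = False
        for other in kept:
            oseq = other.sequence
            if seq and oseq and sequence_identity(seq, oseq) >= threshold:
                duplicate = True
                break
        if not duplicate:
            kept.append(chain)
    return kept
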