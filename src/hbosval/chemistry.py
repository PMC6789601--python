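"""Residue-level chemistry tables shared across the package.

Covers the 20 standard amino acids: one/three-letter codes, heavy-atom
side-chain composition, the gamma atom defining chi1, idealized internal
coordinates used by the synthetic peptide builder, and the distal-block
definitions (the terminal rigid group of each side chain) used for the
block-length feature.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import gemmi

STANDARD_AA: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

#: Backbone atoms never counted as side chain.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: The 18 residue types that carry a chi1 angle and are scored by the model.
#: Glycine and alanine have no gamma atom and are excluded.
SCOREABLE_TYPES: tuple[str, ...] = tuple(
    t for t in STANDARD_AA if t not in ("GLY", "ALA")
)

#: Gamma atom completing chi1 (N-CA-CB-gamma) per residue type.
GAMMA_ATOM: dict[str, str] = {t: "CG" for t in SCOREABLE_TYPES}
GAMMA_ATOM.update({"ILE": "CG1", "VAL": "CG1", "SER": "OG", "THR": "OG1", "CYS": "SG"})


def atomic_mass(element: str) -> float:
    """Standard atomic mass (u) of an element symbol."""
    el = gemmi.Element(element.capitalize() if len(element) > 1 else element)
    if el.name == "X" and element.upper() != "X":
        raise ValueError(f"unknown element symbol: {element!r}")
    return el.weight


# ---------------------------------------------------------------------------
# Idealized side-chain internal coordinates for the peptide builder.
#
# Each entry: (atom, parent, anc2, anc3, bond Å, angle deg, torsion deg)
# meaning bond parent-atom, angle anc2-parent-atom and torsion
# anc3-anc2-parent-atom. A torsion of ("chi1", offset) is resolved at build
# time as the residue's chi1 target plus the offset (gamma-branch atoms).
# Values are textbook idealized geometry; the builder guarantees exact target
# dihedrals, not crystallographic realism.
# ---------------------------------------------------------------------------

Torsion = float | tuple[str, float]
ZEntry = tuple[str, str, str, str, float, float, Torsion]

#: Bond length and angle used to place the gamma atom (CA-CB-gamma frame).
GAMMA_GEOMETRY: dict[str, tuple[float, float]] = {
    "SER": (1.42, 111.1), "THR": (1.43, 109.6), "CYS": (1.81, 113.8),
    "ILE": (1.53, 110.4), "VAL": (1.53, 110.4),
}
_DEFAULT_GAMMA_GEOMETRY = (1.52, 114.1)

SIDECHAIN_TEMPLATES: dict[str, list[ZEntry]] = {
    "ALA": [],
    "GLY": [],
    "SER": [],
    "CYS": [],
    "VAL": [("CG2", "CB", "CA", "N", 1.53, 110.5, ("chi1", 120.0))],
    "THR": [("CG2", "CB", "CA", "N", 1.53, 110.5, ("chi1", 240.0))],
    "ILE": [
        ("CG2", "CB", "CA", "N", 1.53, 110.5, ("chi1", 240.0)),
        ("CD1", "CG1", "CB", "CA", 1.52, 113.8, 180.0),
    ],
    "LEU": [
        ("CD1", "CG", "CB", "CA", 1.52, 110.7, 180.0),
        ("CD2", "CG", "CB", "CA", 1.52, 110.7, 300.0),
    ],
    "PRO": [("CD", "CG", "CB", "CA", 1.51, 106.0, 325.0)],
    "MET": [
        ("SD", "CG", "CB", "CA", 1.81, 112.7, 180.0),
        ("CE", "SD", "CG", "CB", 1.79, 100.2, 180.0),
    ],
    "ASP": [
        ("OD1", "CG", "CB", "CA", 1.25, 118.4, 0.0),
        ("OD2", "CG", "CB", "CA", 1.25, 118.4, 180.0),
    ],
    "ASN": [
        ("OD1", "CG", "CB", "CA", 1.23, 120.8, 0.0),
        ("ND2", "CG", "CB", "CA", 1.33, 116.5, 180.0),
    ],
    "GLU": [
        ("CD", "CG", "CB", "CA", 1.52, 112.6, 180.0),
        ("OE1", "CD", "CG", "CB", 1.25, 118.4, 0.0),
        ("OE2", "CD", "CG", "CB", 1.25, 118.4, 180.0),
    ],
    "GLN": [
        ("CD", "CG", "CB", "CA", 1.52, 112.6, 180.0),
        ("OE1", "CD", "CG", "CB", 1.23, 120.8, 0.0),
        ("NE2", "CD", "CG", "CB", 1.33, 116.5, 180.0),
    ],
    "LYS": [
        ("CD", "CG", "CB", "CA", 1.52, 111.5, 180.0),
        ("CE", "CD", "CG", "CB", 1.52, 111.5, 180.0),
        ("NZ", "CE", "CD", "CG", 1.47, 111.5, 180.0),
    ],
    "ARG": [
        ("CD", "CG", "CB", "CA", 1.52, 111.5, 180.0),
        ("NE", "CD", "CG", "CB", 1.46, 112.0, 180.0),
        ("CZ", "NE", "CD", "CG", 1.33, 124.2, 180.0),
        ("NH1", "CZ", "NE", "CD", 1.33, 120.0, 0.0),
        ("NH2", "CZ", "NE", "CD", 1.33, 120.0, 180.0),
    ],
    "HIS": [
        ("ND1", "CG", "CB", "CA", 1.38, 122.7, 90.0),
        ("CD2", "CG", "CB", "ND1", 1.36, 131.0, 180.0),
        ("CE1", "ND1", "CG", "CD2", 1.32, 108.2, 0.0),
        ("NE2", "CD2", "CG", "ND1", 1.37, 107.2, 0.0),
    ],
    "PHE": [
        ("CD1", "CG", "CB", "CA", 1.39, 120.7, 90.0),
        ("CD2", "CG", "CB", "CD1", 1.39, 120.7, 180.0),
        ("CE1", "CD1", "CG", "CB", 1.39, 120.7, 180.0),
        ("CE2", "CD2", "CG", "CB", 1.39, 120.7, 180.0),
        ("CZ", "CE1", "CD1", "CG", 1.39, 120.0, 0.0),
    ],
    "TYR": [
        ("CD1", "CG", "CB", "CA", 1.39, 120.7, 90.0),
        ("CD2", "CG", "CB", "CD1", 1.39, 120.7, 180.0),
        ("CE1", "CD1", "CG", "CB", 1.39, 120.7, 180.0),
        ("CE2", "CD2", "CG", "CB", 1.39, 120.7, 180.0),
        ("CZ", "CE1", "CD1", "CG", 1.39, 120.0, 0.0),
        ("OH", "CZ", "CE1", "CD1", 1.38, 120.0, 180.0),
    ],
    "TRP": [
        ("CD1", "CG", "CB", "CA", 1.37, 127.0, 90.0),
        ("CD2", "CG", "CB", "CD1", 1.43, 126.6, 180.0),
        ("NE1", "CD1", "CG", "CD2", 1.38, 110.1, 0.0),
        ("CE2", "CD2", "CG", "CD1", 1.41, 107.3, 0.0),
        ("CE3", "CD2", "CG", "CD1", 1.40, 133.9, 180.0),
        ("CZ2", "CE2", "CD2", "CG", 1.40, 122.4, 180.0),
        ("CZ3", "CE3", "CD2", "CE2", 1.39, 118.6, 0.0),
        ("CH2", "CZ2", "CE2", "CD2", 1.37, 117.5, 180.0),
    ],
}

ELEMENT_OF_ATOM_PREFIX = {"C": "C", "N": "N", "O": "O", "S": "S"}


def atom_element(atom_name: str) -> str:
    """Element symbol inferred from a standard amino-acid atom name."""
    return ELEMENT_OF_ATOM_PREFIX[atom_name[0]]


def sidechain_atoms(type3: str) -> frozenset[str]:
    """Expected heavy side-chain atom names for a standard residue type."""
    if type3 == "GLY":
        return frozenset()
    names = {"CB"}
    if type3 in GAMMA_ATOM:
        names.add(GAMMA_ATOM[type3])
    names.update(e[0] for e in SIDECHAIN_TEMPLATES[type3])
    return frozenset(names)


SIDECHAIN_ATOMS: dict[str, frozenset[str]] = {t: sidechain_atoms(t) for t in STANDARD_AA}


# ---------------------------------------------------------------------------
# Distal blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockDefinition:
    """The distal rigid group of one residue type's side chain.

    ``distal_atoms`` is the atom-name list whose mass centroid defines the
    block-length feature; ``chi1_gamma_atom`` completes the chi1 torsion.
    """

    residue_type: str
    distal_atoms: tuple[str, ...]
    chi1_gamma_atom: str

    def __post_init__(self) -> None:
        if not self.distal_atoms:
            raise ValueError(f"{self.residue_type}: empty distal-atom list")
        sc = SIDECHAIN_ATOMS.get(self.residue_type)
        if sc is not None:
            bad = set(self.distal_atoms) - sc
            if bad:
                raise ValueError(
                    f"{self.residue_type}: {sorted(bad)} are not side-chain atoms"
                )


def _default_blocks_path() -> Path:
    return Path(str(importlib.resources.files("hbosval") / "data" / "distal_blocks.tsv"))


def load_blocks(path: str | Path | None = None) -> dict[str, BlockDefinition]:
    """Load the distal-block table from a TSV config.

    Format: three tab-separated columns per line — residue type, gamma atom,
    comma-separated distal atom names. Lines starting with ``#`` are ignored.
    With ``path=None`` the table shipped with the package is used.
    """
    p = Path(path) if path is not None else _default_blocks_path()
    table: dict[str, BlockDefinition] = {}
    for lineno, raw in enumerate(p.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{p}:{lineno}: expected 3 tab-separated fields")
        type3, gamma, distal = parts
        type3 = type3.upper()
        if type3 in table:
            raise ValueError(f"{p}:{lineno}: duplicate entry for {type3}")
        table[type3] = BlockDefinition(
            residue_type=type3,
            distal_atoms=tuple(a.strip() for a in distal.split(",") if a.strip()),
            chi1_gamma_atom=gamma.strip(),
        )
    missing = set(SCOREABLE_TYPES) - set(table)
    if missing:
        raise ValueError(f"{p}: missing block definitions for {sorted(missing)}")
    return table
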