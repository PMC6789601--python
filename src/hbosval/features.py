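"""Per-residue conformational features.

Five features describe a residue's conformation: the backbone torsions phi
and psi, the first side-chain torsion chi1, the side-chain size (CA to the
mass centroid of all heavy side-chain atoms) and the block length (CA to the
mass centroid of the side chain's distal rigid group). Torsions are reported
on a 0-360 degree scale. A feature that cannot be computed (chain terminus,
chain break, missing atoms) is None and propagates as "missing" downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemistry import (
    BACKBONE_ATOMS,
    BlockDefinition,
    GAMMA_ATOM,
    SCOREABLE_TYPES,
    SIDECHAIN_ATOMS,
    atomic_mass,
    load_blocks,
)
from .structure_io import Atom, Chain, Residue

__all__ = [
    "FEATURES", "FeatureVector", "DegenerateGeometryError",
    "dihedral_deg", "compute_phi", "compute_psi", "compute_chi1",
    "mass_centroid", "compute_d_sidechain", "compute_d_block",
    "extract_features",
]

#: Canonical feature order used throughout the package.
FEATURES: tuple[str, ...] = ("phi", "psi", "chi1", "d_sidechain", "d_block")

#: Maximum C(i-1)-N(i) distance (Å) for two residues to count as bonded;
#: torsions across a longer gap are treated as missing.
PEPTIDE_BOND_CUTOFF = 2.0


class DegenerateGeometryError(ValueError):
    """Raised when a dihedral is requested for collinear/coincident points."""


@dataclass
class FeatureVector:
    """The five feature values of one residue; None marks a missing value."""

    residue_type: str
    residue_index: int
    icode: str
    chain_id: str
    phi: float | None = None
    psi: float | None = None
    chi1: float | None = None
    d_sidechain: float | None = None
    d_block: float | None = None

    def value(self, feature: str) -> float | None:
        return getattr(self, feature)

    @property
    def label(self) -> str:
        return f"{self.residue_index}{self.icode}".strip()

    @property
    def complete(self) -> bool:
        return all(self.value(f) is not None for f in FEATURES)


def dihedral_deg(p1, p2, p3, p4) -> float:
    """Torsion angle of four points, in degrees on [0, 360).

    The signed IUPAC dihedral in (-180, 180] is computed from the usual
    cross-product construction, then negatives are shifted by +360.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if norm_b2 < 1e-12 or np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise DegenerateGeometryError(
            f"collinear or coincident points: {p1}, {p2}, {p3}, {p4}"
        )
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / norm_b2)
    ang = np.degrees(np.arctan2(y, x))
    if ang < 0.0:
        ang += 360.0
    return ang % 360.0


def _bonded(prev: Residue, cur: Residue) -> bool:
    c_prev = prev.position("C")
    n_cur = cur.position("N")
    if c_prev is None or n_cur is None:
        return False
    return float(np.linalg.norm(c_prev - n_cur)) <= PEPTIDE_BOND_CUTOFF


def compute_phi(prev: Residue | None, cur: Residue) -> float | None:
    """Backbone torsion C(i-1)-N-CA-C, or None at the N-terminus / a break."""
    if prev is None or not _bonded(prev, cur):
        return None
    pts = (prev.position("C"), cur.position("N"), cur.position("CA"), cur.position("C"))
    if any(p is None for p in pts):
        return None
    return dihedral_deg(*pts)


def compute_psi(cur: Residue, nxt: Residue | None) -> float | None:
    """Backbone torsion N-CA-C-N(i+1), or None at the C-terminus / a break."""
    if nxt is None or not _bonded(cur, nxt):
        return None
    pts = (cur.position("N"), cur.position("CA"), cur.position("C"), nxt.position("N"))
    if any(p is None for p in pts):
        return None
    return dihedral_deg(*pts)


def compute_chi1(cur: Residue, blocks: dict[str, BlockDefinition] | None = None) -> float | None:
    """First side-chain torsion N-CA-CB-gamma; None for GLY/ALA or missing atoms."""
    gamma = GAMMA_ATOM.get(cur.type3)
    if blocks is not None and cur.type3 in blocks:
        gamma = blocks[cur.type3].chi1_gamma_atom
    if gamma is None:
        return None
    pts = (cur.position("N"), cur.position("CA"), cur.position("CB"), cur.position(gamma))
    if any(p is None for p in pts):
        return None
    return dihedral_deg(*pts)


def mass_centroid(atoms: list[Atom]) -> np.ndarray:
    """Mass-weighted centroid of a non-empty atom list (standard atomic masses)."""
    if not atoms:
        raise ValueError("mass_centroid of an empty atom list")
    masses = np.array([atomic_mass(a.element) for a in atoms])
    coords = np.stack([a.position for a in atoms])
    return (masses[:, None] * coords).sum(axis=0) / masses.sum()


def _sidechain_heavy_atoms(res: Residue) -> list[Atom]:
    return [
        a for name, a in res.atoms.items()
        if name not in BACKBONE_ATOMS and a.element != "H" and a.element != "D"
    ]


def compute_d_sidechain(cur: Residue) -> float | None:
    """Distance (Å) from CA to the mass centroid of all heavy side-chain atoms.

    None if CA is absent, the residue has no side chain, or the side chain is
    incomplete relative to the residue type's chemical definition.
    """
    ca = cur.position("CA")
    if ca is None:
        return None
    side = _sidechain_heavy_atoms(cur)
    if not side:
        return None
    expected = SIDECHAIN_ATOMS.get(cur.type3)
    if expected is not None and not expected <= {a.name for a in side}:
        return None
    return float(np.linalg.norm(mass_centroid(side) - ca))


def compute_d_block(cur: Residue, blocks: dict[str, BlockDefinition]) -> float | None:
    """Distance (Å) from CA to the mass centroid of the distal block.

    None when CA or any distal atom is absent; raises KeyError for a residue
    type absent from the block table.
    """
    block = blocks.get(cur.type3)
    if block is None:
        raise KeyError(f"no distal-block definition for residue type {cur.type3!r}")
    ca = cur.position("CA")
    if ca is None:
        return None
    atoms = [cur.get(name) for name in block.distal_atoms]
    if any(a is None for a in atoms):
        return None
    return float(np.linalg.norm(mass_centroid(atoms) - ca))


def extract_features(
    chain: Chain, blocks: dict[str, BlockDefinition] | None = None
) -> list[FeatureVector]:
    """Feature vectors for every scoreable residue of a chain, in order.

    GLY and ALA (no chi1) and nonstandard residues are excluded; missing
    values are carried as None. Neighbours for phi/psi are the flanking
    residues in file order, subject to the peptide-bond distance check.
    """
    if blocks is None:
        blocks = load_blocks()
    out: list[FeatureVector] = []
    residues = chain.residues
    for i, res in enumerate(residues):
        if res.type3 not in SCOREABLE_TYPES:
            continue
        prev = residues[i - 1] if i > 0 else None
        nxt = residues[i + 1] if i + 1 < len(residues) else None
        out.append(
            FeatureVector(
                residue_type=res.type3,
                residue_index=res.index,
                icode=res.icode,
                chain_id=chain.id,
                phi=compute_phi(prev, res),
                psi=compute_psi(res, nxt),
                chi1=compute_chi1(res, blocks),
                d_sidechain=compute_d_sidechain(res),
                d_block=compute_d_block(res, blocks),
            )
        )
    return out
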