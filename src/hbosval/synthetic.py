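"""Geometry-controlled synthetic peptides and feature samples.

The builder places atoms by sequential internal-coordinate extension (the
natural-extension reference frame): every atom is positioned from a bond
length, a bond angle and a torsion relative to three previously placed atoms,
so requested backbone and chi1 torsions are honored exactly. Side chains
beyond the gamma atom use idealized template geometry. The resulting chains
are chemically idealized test objects, not physically packed conformers:
there is no clash avoidance and the proline ring is left unclosed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .chemistry import (
    GAMMA_ATOM,
    GAMMA_GEOMETRY,
    _DEFAULT_GAMMA_GEOMETRY,
    ONE_TO_THREE,
    SIDECHAIN_TEMPLATES,
    atom_element,
)
from .structure_io import Atom, Chain, Residue, Structure

__all__ = [
    "PeptideSpec", "FeatureSampleSpec", "place_atom", "build_peptide",
    "write_pdb", "sample_features", "make_outlier_corpus",
]

# Idealized backbone geometry (Å, degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
# Improper torsion C-N-CA-CB placing CB with L-chirality (0-360 scale).
TORSION_C_N_CA_CB = 237.4
BOND_CA_CB = 1.53
ANGLE_N_CA_CB = 110.5

DEFAULT_OMEGA = 180.0
DEFAULT_PHI = 300.0
DEFAULT_PSI = 320.0
DEFAULT_CHI1 = 180.0


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place a new atom D bonded to c with |cD| = bond, angle(b,c,D) and
    torsion(a,b,c,D) as requested (NeRF construction)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-10:
        raise ValueError("reference atoms are collinear; cannot define a frame")
    n /= n_norm
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-math.cos(ang), math.sin(ang) * math.cos(tor), math.sin(ang) * math.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass
class PeptideSpec:
    """Recipe for one synthetic chain.

    Per-residue target lists must match the sequence length; None entries
    fall back to defaults (omega 180, extended-ish phi/psi, chi1 180).
    Angles are degrees on [0, 360). ``jitter_sd`` adds isotropic Gaussian
    noise (Å) to every coordinate, seeded for reproducibility.
    """

    sequence: str
    phi: Sequence[float | None] | None = None
    psi: Sequence[float | None] | None = None
    omega: Sequence[float | None] | None = None
    chi1: Sequence[float | None] | None = None
    chain_id: str = "A"
    start_index: int = 1
    jitter_sd: float = 0.0
    seed: int = 0

    def _target(self, values, i: int, default: float) -> float:
        if values is None or i >= len(values) or values[i] is None:
            return default
        v = float(values[i])
        if not 0.0 <= v < 360.0:
            v %= 360.0
        return v

    def targets(self, i: int) -> tuple[float, float, float, float]:
        return (
            self._target(self.phi, i, DEFAULT_PHI),
            self._target(self.psi, i, DEFAULT_PSI),
            self._target(self.omega, i, DEFAULT_OMEGA),
            self._target(self.chi1, i, DEFAULT_CHI1),
        )


def _build_sidechain(pos: dict[str, np.ndarray], type3: str, chi1: float) -> None:
    if type3 == "GLY":
        return
    pos["CB"] = place_atom(pos["C"], pos["N"], pos["CA"],
                           BOND_CA_CB, ANGLE_N_CA_CB, TORSION_C_N_CA_CB)
    gamma = GAMMA_ATOM.get(type3)
    if gamma is not None:
        bond, angle = GAMMA_GEOMETRY.get(type3, _DEFAULT_GAMMA_GEOMETRY)
        pos[gamma] = place_atom(pos["N"], pos["CA"], pos["CB"], bond, angle, chi1)
    for name, parent, anc2, anc3, bond, angle, torsion in SIDECHAIN_TEMPLATES[type3]:
        if isinstance(torsion, tuple):
            torsion = (chi1 + torsion[1]) % 360.0
        pos[name] = place_atom(pos[anc3], pos[anc2], pos[parent], bond, angle, torsion)


def build_peptide(spec: PeptideSpec) -> Structure:
    """Build a Structure from a PeptideSpec by internal-coordinate extension."""
    seq = spec.sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = [c for c in seq if c not in ONE_TO_THREE]
    if bad:
        raise ValueError(f"unsupported residue letter(s): {sorted(set(bad))}")

    per_res: list[dict[str, np.ndarray]] = []
    prev: dict[str, np.ndarray] | None = None
    for i, letter in enumerate(seq):
        phi, psi, omega, chi1 = spec.targets(i)
        pos: dict[str, np.ndarray] = {}
        if prev is None:
            pos["N"] = np.zeros(3)
            pos["CA"] = np.array([BOND_N_CA, 0.0, 0.0])
            pos["C"] = place_atom(np.array([0.0, -1.0, 0.0]), pos["N"], pos["CA"],
                                  BOND_CA_C, ANGLE_N_CA_C, 0.0)
        else:
            _, prev_psi, prev_omega, _ = spec.targets(i - 1)
            pos["N"] = place_atom(prev["N"], prev["CA"], prev["C"],
                                  BOND_C_N, ANGLE_CA_C_N, prev_psi)
            pos["CA"] = place_atom(prev["CA"], prev["C"], pos["N"],
                                   BOND_N_CA, ANGLE_C_N_CA, prev_omega)
            pos["C"] = place_atom(prev["C"], pos["N"], pos["CA"],
                                  BOND_CA_C, ANGLE_N_CA_C, phi)
            # carbonyl O of the previous residue, trans to the new amide N
            prev["O"] = place_atom(pos["N"], prev["CA"], prev["C"],
                                   BOND_C_O, ANGLE_CA_C_O, 180.0)
        _build_sidechain(pos, ONE_TO_THREE[letter], chi1)
        per_res.append(pos)
        prev = pos
    # C-terminal carbonyl from the residue's own psi target
    _, last_psi, _, _ = spec.targets(len(seq) - 1)
    prev["O"] = place_atom(prev["N"], prev["CA"], prev["C"],
                           BOND_C_O, ANGLE_CA_C_O, (last_psi + 180.0) % 360.0)

    rng = np.random.default_rng(spec.seed)
    chain = Chain(id=spec.chain_id)
    for i, (letter, pos) in enumerate(zip(seq, per_res)):
        type3 = ONE_TO_THREE[letter]
        res = Residue(type3=type3, index=spec.start_index + i)
        order = ["N", "CA", "C", "O"] + [n for n in pos if n not in ("N", "CA", "C", "O")]
        for name in order:
            xyz = pos[name]
            if spec.jitter_sd > 0:
                xyz = xyz + rng.normal(0.0, spec.jitter_sd, 3)
            res.atoms[name] = Atom(name=name, element=atom_element(name), position=xyz)
        chain.residues.append(res)
    return Structure(id="synthetic", chains=[chain], source_path="")


def write_pdb(structure: Structure, path: str | Path) -> Path:
    """Write a Structure as standards-conformant PDB text (ATOM/TER/END)."""
    if not structure.chains or not any(c.residues for c in structure.chains):
        raise ValueError("refusing to write an empty structure")
    lines: list[str] = []
    serial = 1
    for chain in structure.chains:
        last = None
        for res in chain.residues:
            for atom in res.atoms.values():
                x, y, z = atom.position
                if not all(-999.999 <= v <= 9999.999 for v in (x, y, z)):
                    raise ValueError(
                        f"coordinate out of PDB fixed-column range: {atom.position}"
                    )
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s}{atom.altloc or ' ':1s}"
                    f"{res.type3:>3s} {chain.id:1s}{res.index:4d}{res.icode or ' ':1s}"
                    f"   {x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
            last = res
        if last is not None:
            lines.append(
                f"TER   {serial:5d}      {last.type3:>3s} "
                f"{chain.id:1s}{last.index:4d}{last.icode or ' ':1s}"
            )
            serial += 1
    lines.append("END")
    p = Path(path)
    p.write_text("\n".join(lines) + "\n")
    return p


@dataclass
class FeatureSampleSpec:
    """Mixture recipe for synthetic feature-value samples.

    ``components`` is a list of (mode, sd, weight); weights must sum to 1.
    Angular features are sampled wrapped-normal onto [0, 360); distances are
    plain normals truncated at 0.
    """

    residue_type: str
    feature: str
    components: list[tuple[float, float, float]]
    n: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        w = sum(c[2] for c in self.components)
        if not math.isclose(w, 1.0, abs_tol=1e-9):
            raise ValueError(f"mixture weights sum to {w}, expected 1")


def sample_features(spec: FeatureSampleSpec) -> np.ndarray:
    """Draw n values from the mixture, reproducibly by seed."""
    rng = np.random.default_rng(spec.seed)
    weights = np.array([c[2] for c in spec.components])
    which = rng.choice(len(spec.components), size=spec.n, p=weights)
    out = np.empty(spec.n)
    angular = spec.feature in ("phi", "psi", "chi1")
    for i, k in enumerate(which):
        mode, sd, _ = spec.components[k]
        v = rng.normal(mode, sd)
        out[i] = v % 360.0 if angular else max(v, 0.0)
    return out


# Canonical dihedral modes (degrees) for the outlier corpus: a tight,
# unimodal helix-like conformation per feature.
_CANON = {"phi": 300.0, "psi": 320.0, "chi1": 300.0}
_CANON_SD = 8.0
# Planted conformations: far outside the canonical modes, so their bins have
# zero reference density and each violated torsion scores the floor penalty.
_PLANT = {"phi": 120.0, "psi": 80.0, "chi1": 180.0}

_SCOREABLE_LETTERS = "".join(
    letter for letter, t3 in ONE_TO_THREE.items() if t3 not in ("GLY", "ALA")
)


def _random_peptide(rng: np.random.Generator, length: int, chain_id: str = "A",
                    jitter_sd: float = 0.01) -> PeptideSpec:
    seq = "".join(rng.choice(list(_SCOREABLE_LETTERS), size=length))
    return PeptideSpec(
        sequence=seq,
        phi=list(rng.normal(_CANON["phi"], _CANON_SD, length) % 360.0),
        psi=list(rng.normal(_CANON["psi"], _CANON_SD, length) % 360.0),
        chi1=list(rng.normal(_CANON["chi1"], _CANON_SD, length) % 360.0),
        chain_id=chain_id,
        jitter_sd=jitter_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def make_outlier_corpus(
    seed: int,
    n_reference: int = 200,
    n_probe: int = 60,
    length: int = 10,
    n_planted: int = 20,
) -> tuple[list[Structure], list[Structure], list[tuple[int, str, int]]]:
    """Reference peptides, probe peptides with planted outliers, truth labels.

    Reference chains are drawn from tight canonical dihedral modes. Probe
    chains come from the same distribution except for ``n_planted`` interior
    residues rebuilt at conformations with zero reference density (all three
    torsions violated, so the floor rule guarantees a total of at least 15).
    Truth labels are (probe index, chain id, residue index) triples.
    """
    rng = np.random.default_rng(seed)
    reference = [build_peptide(_random_peptide(rng, length)) for _ in range(n_reference)]

    probe_specs = [_random_peptide(rng, length) for _ in range(n_probe)]
    truth: list[tuple[int, str, int]] = []
    slots = [(p, r) for p in range(n_probe) for r in range(1, length - 1)]
    chosen = rng.choice(len(slots), size=n_planted, replace=False)
    for si in sorted(int(c) for c in chosen):
        p, r = slots[si]
        spec = probe_specs[p]
        spec.phi[r] = _PLANT["phi"]
        spec.psi[r] = _PLANT["psi"]
        spec.chi1[r] = _PLANT["chi1"]
        truth.append((p, spec.chain_id, spec.start_index + r))
    probes = [build_peptide(s) for s in probe_specs]
    return reference, probes, truth
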