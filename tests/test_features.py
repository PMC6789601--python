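"""Dihedrals, centroids and the five per-residue features."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from hbosval.chemistry import load_blocks
from hbosval.features import (
    DegenerateGeometryError,
    compute_chi1,
    compute_d_block,
    compute_d_sidechain,
    compute_phi,
    compute_psi,
    dihedral_deg,
    extract_features,
    mass_centroid,
)
from hbosval.structure_io import Atom, Residue
from hbosval.synthetic import PeptideSpec, build_peptide

BLOCKS = load_blocks()


def _atom(name, pos, element=None):
    return Atom(name=name, element=element or name[0], position=np.array(pos, float))


@pytest.mark.parametrize(
    "p4, expected",
    [
        ((1, 1, 0), 0.0),     # eclipsed / cis
        ((-1, 1, 0), 180.0),  # trans
        ((0, 1, 1), 270.0),   # verified against an independent dihedral oracle
    ],
)
def test_dihedral_reference_configurations(p4, expected):
    assert dihedral_deg((1, 0, 0), (0, 0, 0), (0, 1, 0), p4) == pytest.approx(expected)


def test_dihedral_rejects_collinear():
    with pytest.raises(DegenerateGeometryError):
        dihedral_deg((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


angles = st.floats(min_value=0.0, max_value=359.999)
coords = st.floats(min_value=-50, max_value=50)
points = st.tuples(coords, coords, coords)


@settings(deadline=None, max_examples=100)
@given(points, points, points, points)
def test_dihedral_range_and_reversal(p1, p2, p3, p4):
    pts = np.array([p1, p2, p3, p4])
    n1 = np.cross(pts[1] - pts[0], pts[2] - pts[1])
    n2 = np.cross(pts[2] - pts[1], pts[3] - pts[2])
    # well-conditioned frames only; collinear triples are a documented error
    assume(np.linalg.norm(n1) > 1e-3 and np.linalg.norm(n2) > 1e-3)
    d = dihedral_deg(p1, p2, p3, p4)
    rev = dihedral_deg(p4, p3, p2, p1)
    assert 0.0 <= d < 360.0
    # the IUPAC torsion is invariant under full reversal of the four points
    wrapped = (d - rev) % 360.0
    assert min(wrapped, 360.0 - wrapped) == pytest.approx(0.0, abs=1e-3)


def test_phi_psi_chi1_roundtrip_and_termini():
    spec = PeptideSpec(
        "EEE", phi=[None, 252.3, None], psi=[None, 134.5, None], chi1=[None, 286.0, None]
    )
    chain = build_peptide(spec).chains[0]
    r0, r1, r2 = chain.residues
    assert compute_phi(None, r0) is None           # N-terminus
    assert compute_psi(r2, None) is None           # C-terminus
    assert compute_phi(r0, r1) == pytest.approx(252.3, abs=1e-4)
    assert compute_psi(r1, r2) == pytest.approx(134.5, abs=1e-4)
    assert compute_chi1(r1, BLOCKS) == pytest.approx(286.0, abs=1e-4)


def test_missing_atoms_give_missing_features():
    chain = build_peptide(PeptideSpec("ELE")).chains[0]
    r0, r1, r2 = chain.residues
    del r1.atoms["N"]
    assert compute_phi(r0, r1) is None
    del r1.atoms["CG"]
    assert compute_chi1(r1, BLOCKS) is None


def test_chain_break_gives_missing_torsions():
    chain = build_peptide(PeptideSpec("EEE")).chains[0]
    r0, r1, r2 = chain.residues
    for a in r2.atoms.values():  # shift the third residue far away
        a.position = a.position + np.array([50.0, 0.0, 0.0])
    assert compute_psi(r1, r2) is None
    assert compute_phi(r1, r2) is None


def test_gly_and_ala_have_no_chi1():
    chain = build_peptide(PeptideSpec("GAG")).chains[0]
    for res in chain.residues:
        assert compute_chi1(res, BLOCKS) is None


def test_mass_centroid():
    assert np.allclose(mass_centroid([_atom("CA", (1, 2, 3), "C")]), [1, 2, 3])
    two_c = [_atom("C1", (0, 0, 0), "C"), _atom("C2", (2, 0, 0), "C")]
    assert np.allclose(mass_centroid(two_c), [1, 0, 0])
    co = [_atom("C", (0, 0, 0), "C"), _atom("O", (1, 0, 0), "O")]
    # hand-computed weighted mean: 15.999 / (12.011 + 15.999)
    assert mass_centroid(co)[0] == pytest.approx(0.5712, abs=2e-4)
    with pytest.raises(ValueError):
        mass_centroid([])


def test_d_sidechain_ala_equals_ca_cb_distance():
    chain = build_peptide(PeptideSpec("GAG")).chains[0]
    ala = chain.residues[1]
    d = compute_d_sidechain(ala)
    expected = np.linalg.norm(ala.atoms["CA"].position - ala.atoms["CB"].position)
    assert d == pytest.approx(expected, abs=1e-9)


def test_d_sidechain_independent_arithmetic_oracle():
    chain = build_peptide(PeptideSpec("ELE")).chains[0]
    leu = chain.residues[1]
    import gemmi

    side = [leu.atoms[n] for n in ("CB", "CG", "CD1", "CD2")]
    masses = [gemmi.Element(a.element).weight for a in side]
    cen = sum(m * a.position for m, a in zip(masses, side)) / sum(masses)
    expected = math.dist(cen, leu.atoms["CA"].position)
    assert compute_d_sidechain(leu) == pytest.approx(expected, abs=1e-6)


def test_d_sidechain_missing_when_incomplete():
    chain = build_peptide(PeptideSpec("ELE")).chains[0]
    leu = chain.residues[1]
    del leu.atoms["CD2"]
    assert compute_d_sidechain(leu) is None
    for name in ("CB", "CG", "CD1"):
        del leu.atoms[name]
    assert compute_d_sidechain(leu) is None


def test_d_block_equal_mass_arithmetic():
    res = Residue(type3="LEU", index=1)
    res.atoms = {
        "CA": _atom("CA", (0, 0, 0)),
        "CG": _atom("CG", (2.5, 0, 0)),
        "CD1": _atom("CD1", (3.2, 1, 0)),
        "CD2": _atom("CD2", (3.2, -1, 0)),
    }
    # equal-mass centroid (2.9667, 0, 0): distance from origin
    assert compute_d_block(res, BLOCKS) == pytest.approx(2.9667, abs=1e-3)


def test_d_block_missing_atom_and_unknown_type():
    chain = build_peptide(PeptideSpec("EEE")).chains[0]
    glu = chain.residues[1]
    del glu.atoms["OE2"]
    assert compute_d_block(glu, BLOCKS) is None
    with pytest.raises(KeyError):
        compute_d_block(Residue(type3="MSE", index=1), BLOCKS)


def test_extract_features_excludes_gly_ala():
    chain = build_peptide(PeptideSpec("ACDEF")).chains[0]
    fvs = extract_features(chain, BLOCKS)
    assert [fv.residue_type for fv in fvs] == ["CYS", "ASP", "GLU", "PHE"]
    chain = build_peptide(PeptideSpec("GGGG")).chains[0]
    assert extract_features(chain, BLOCKS) == []


def test_rigid_transform_invariance(rng):
    chain = build_peptide(PeptideSpec("QWERTY", chi1=[300.0] * 6)).chains[0]
    before = extract_features(chain, BLOCKS)
    # random rotation (QR of a Gaussian matrix) + translation
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.normal(size=3) * 10
    for res in chain.residues:
        for a in res.atoms.values():
            a.position = q @ a.position + t
    after = extract_features(chain, BLOCKS)
    for fv0, fv1 in zip(before, after):
        for feat in ("phi", "psi", "chi1"):
            v0, v1 = fv0.value(feat), fv1.value(feat)
            if v0 is None:
                assert v1 is None
            else:
                assert abs(v0 - v1) % 360 == pytest.approx(0, abs=1e-6)
        for feat in ("d_sidechain", "d_block"):
            assert fv1.value(feat) == pytest.approx(fv0.value(feat), abs=1e-6)


def test_d_block_bounded_by_max_distal_distance():
    chain = build_peptide(PeptideSpec("RKWFY", chi1=[180.0] * 5)).chains[0]
    for res, fv in zip(
        [r for r in chain.residues], extract_features(chain, BLOCKS)
    ):
        ca = res.atoms["CA"].position
        dists = [
            np.linalg.norm(res.atoms[n].position - ca)
            for n in BLOCKS[res.type3].distal_atoms
        ]
        assert fv.d_block <= max(dists) + 1e-9
        assert fv.d_sidechain > 0
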