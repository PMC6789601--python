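"""HBOS component arithmetic, residue scoring, thresholds, distributions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hbosval.features import FEATURES, FeatureVector
from hbosval.reference import HistogramBuilder, accumulate, lookup_npdf
from hbosval.scoring import (
    ScoringParams,
    hbos_component,
    hbos_distribution,
    score_chain,
    score_residue,
)
from hbosval.synthetic import PeptideSpec, build_peptide

PARAMS = ScoringParams()


def _fv(type3="GLN", **values):
    base = dict(phi=300.0, psi=320.0, chi1=300.0, d_sidechain=3.0, d_block=4.0)
    base.update(values)
    return FeatureVector(residue_type=type3, residue_index=1, icode="", chain_id="A", **base)


def _db_with(phi_density):
    """A DB whose GLN phi table follows ``phi_density``; all defaults peak."""
    b = HistogramBuilder()
    accumulate([_fv()], b)  # put every default value in a peak bin
    db = b.finalize()
    db.tables[("GLN", "phi")].density = np.asarray(phi_density, dtype=float)
    return db


def test_component_reference_values():
    assert hbos_component(1.0, PARAMS) == 0.0
    assert hbos_component(0.0005, PARAMS) == 5.0     # below the floor
    assert hbos_component(0.0, PARAMS) == 5.0
    assert hbos_component(0.01, PARAMS) == pytest.approx(2.0, abs=1e-12)
    # density exactly at the floor takes the logarithm, not the penalty
    assert hbos_component(0.001, PARAMS) == pytest.approx(3.0, abs=1e-12)


def test_component_domain_error():
    with pytest.raises(ValueError):
        hbos_component(1.5, PARAMS)
    with pytest.raises(ValueError):
        hbos_component(-0.1, PARAMS)


def test_params_floor_must_be_a_penalty():
    with pytest.raises(ValueError):
        ScoringParams(npdf_floor=0.001, floor_score=2.0)


@settings(deadline=None, max_examples=200)
@given(st.floats(min_value=0.001, max_value=1.0), st.floats(min_value=0.001, max_value=1.0))
def test_component_monotone_nonincreasing(a, b):
    lo, hi = min(a, b), max(a, b)
    assert hbos_component(lo, PARAMS) >= hbos_component(hi, PARAMS) - 1e-12


def test_all_peak_bins_score_zero(reference_db):
    # pick values at the peak bin of each GLN table
    values = {}
    for f in FEATURES:
        t = reference_db.table("GLN", f)
        peak = int(np.argmax(t.density))
        values[f] = t.bins.lower + (peak + 0.5) * t.bins.width
    s = score_residue(_fv(**values), reference_db, PARAMS)
    assert s.total == pytest.approx(0.0)
    assert not s.is_outlier
    assert s.flagged_features == ()


def test_missing_feature_is_not_scored(reference_db):
    s = score_residue(_fv(phi=None), reference_db, PARAMS)
    assert s.total is None
    assert not s.scored
    assert not s.is_outlier
    assert s.missing_features == ("phi",)


def test_outlier_threshold_is_strict():
    from hbosval.reference import bin_index

    # densities chosen so each component is exactly 2 -> total exactly 10
    db = _db_with([0.01] * 72)
    fv = _fv()
    for f, val in (("psi", 320.0), ("chi1", 300.0), ("d_sidechain", 3.0), ("d_block", 4.0)):
        t = db.tables[("GLN", f)]
        idx = bin_index(val, t.bins)
        t.density[:] = 0.0
        t.density[idx] = 0.01
        t.density[0 if idx != 0 else 1] = 1.0
    s = score_residue(fv, db, PARAMS)
    assert s.total == pytest.approx(10.0, abs=1e-9)
    assert not s.is_outlier           # strictly greater than 10 required
    # nudge one density down: total just above 10 -> outlier
    t = db.tables[("GLN", "phi")]
    t.density[:] = 0.009
    t.density[0] = 1.0
    s2 = score_residue(fv, db, PARAMS)
    assert s2.total > 10.0
    assert s2.is_outlier


def test_flagged_features(reference_db):
    db = _db_with([0.005] * 72)   # phi component log10(200) = 2.301 > 2
    s = score_residue(_fv(), db, PARAMS)
    assert "phi" in s.flagged_features
    assert s.components.phi == pytest.approx(math.log10(200.0))


def test_score_matches_bruteforce_oracle(reference_db, rng):
    """Totals equal an inline reimplementation (lookup + log) to 1e-12."""
    for _ in range(200):
        fv = _fv(
            phi=float(rng.uniform(0, 360)),
            psi=float(rng.uniform(0, 360)),
            chi1=float(rng.uniform(0, 360)),
            d_sidechain=float(rng.uniform(0, 12)),
            d_block=float(rng.uniform(0, 12)),
        )
        s = score_residue(fv, reference_db, PARAMS)
        expected = 0.0
        for f in FEATURES:
            d = lookup_npdf(reference_db, "GLN", f, fv.value(f))
            expected += 5.0 if d < 0.001 else math.log10(1.0 / d)
        assert s.total == pytest.approx(expected, abs=1e-12)
        assert all(
            0.0 <= s.components.value(f) <= 5.0 for f in FEATURES
        )
        assert 0.0 <= s.total <= 25.0


def test_score_chain_order_determinism_and_gly(reference_db):
    chain = build_peptide(PeptideSpec("GQEG")).chains[0]
    s1 = score_chain(chain, reference_db)
    s2 = score_chain(chain, reference_db)
    assert [x.residue_type for x in s1] == ["GLN", "GLU"]
    assert [x.total for x in s1] == [x.total for x in s2]
    gly_only = build_peptide(PeptideSpec("GGGG")).chains[0]
    assert score_chain(gly_only, reference_db) == []


def test_planted_conformation_scores_floor(reference_db, corpus):
    _, probes, truth = corpus
    p, chain_id, idx = truth[0]
    chain = probes[p].chain(chain_id)
    scores = {s.residue_index: s for s in score_chain(chain, reference_db)}
    s = scores[idx]
    assert s.total >= 5.0
    assert set(s.flagged_features) >= {"phi", "psi", "chi1"}


def _score_like(total):
    from hbosval.scoring import HbosComponents, ResidueScore

    return ResidueScore(
        residue_type="GLN", residue_index=1, icode="", chain_id="A",
        components=HbosComponents(), total=total, is_outlier=False,
        flagged_features=(),
    )


def test_hbos_distribution():
    edges, mass = hbos_distribution([_score_like(0.0)] * 3)
    assert mass.sum() == pytest.approx(1.0)
    assert mass[0] == 1.0
    edges, mass = hbos_distribution(
        [_score_like(0.05), _score_like(0.05), _score_like(9.95)]
    )
    assert mass[0] == pytest.approx(2 / 3)
    assert mass[99] == pytest.approx(1 / 3)
    assert mass.sum() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        hbos_distribution([])
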