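"""Histogram-based outlier scoring of residues.

Each feature value v_i of a residue is scored HBOS(i) = log10(1 / npdf_i(v_i)),
where npdf_i is the peak-normalized histogram density of that residue type's
feature in the reference database. A density below the floor (default 0.001)
would blow up the logarithm, so such bins score a fixed penalty (default 5).
The residue score is the sum of the five components; residues whose total
exceeds the outlier threshold (default 10, strict) are labeled outliers.
Components above the flag threshold (default 2, i.e. density below 1% of the
peak) mark the individual feature as highly unfavorable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chemistry import BlockDefinition, SCOREABLE_TYPES, load_blocks
from .features import FEATURES, FeatureVector, extract_features
from .reference import ReferenceDB, lookup_npdf
from .structure_io import Chain

__all__ = [
    "ScoringParams", "HbosComponents", "ResidueScore",
    "hbos_component", "score_residue", "score_chain", "hbos_distribution",
]


@dataclass(frozen=True)
class ScoringParams:
    """Thresholds and constants of the scoring rule.

    The floor must be at least as punishing as the log it replaces:
    floor_score >= log(1/npdf_floor) in the chosen base.
    """

    outlier_threshold: float = 10.0
    flag_threshold: float = 2.0
    npdf_floor: float = 0.001
    floor_score: float = 5.0
    log_base: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.npdf_floor < 1:
            raise ValueError("npdf_floor must lie in (0, 1)")
        if self.log_base <= 1:
            raise ValueError("log_base must exceed 1")
        if self.floor_score < math.log(1 / self.npdf_floor, self.log_base):
            raise ValueError(
                "floor_score must be >= log(1/npdf_floor) so the floor is a "
                "penalty, not a discount"
            )


def hbos_component(npdf_value: float, params: ScoringParams = ScoringParams()) -> float:
    """Score one feature from its npdf density.

    Density below the floor scores the fixed floor penalty; otherwise
    log(1/density) in the configured base (0 at a peak bin).
    """
    if not 0.0 <= npdf_value <= 1.0:
        raise ValueError(f"npdf value {npdf_value} outside [0, 1]")
    if npdf_value < params.npdf_floor:
        return params.floor_score
    return math.log(1.0 / npdf_value, params.log_base)


@dataclass
class HbosComponents:
    """Per-feature HBOS values; None where the feature itself was missing."""

    phi: float | None = None
    psi: float | None = None
    chi1: float | None = None
    d_sidechain: float | None = None
    d_block: float | None = None
    floor_applied: dict[str, bool] = field(default_factory=dict)

    def value(self, feature: str) -> float | None:
        return getattr(self, feature)

    def as_dict(self) -> dict[str, float | None]:
        return {f: self.value(f) for f in FEATURES}


@dataclass
class ResidueScore:
    """Scoring outcome for one residue.

    ``total`` is None when any feature was missing (the residue is reported
    as unscored, never silently safe or outlier). ``flagged_features`` lists
    features whose component exceeds the flag threshold.
    """

    residue_type: str
    residue_index: int
    icode: str
    chain_id: str
    components: HbosComponents
    total: float | None
    is_outlier: bool
    flagged_features: tuple[str, ...]
    missing_features: tuple[str, ...] = ()

    @property
    def scored(self) -> bool:
        return self.total is not None

    @property
    def label(self) -> str:
        return f"{self.residue_index}{self.icode}".strip()


def score_residue(
    fv: FeatureVector, db: ReferenceDB, params: ScoringParams = ScoringParams()
) -> ResidueScore:
    """Score one feature vector against the reference database."""
    if fv.residue_type not in SCOREABLE_TYPES:
        raise ValueError(f"residue type {fv.residue_type} is not scoreable")
    comps = HbosComponents()
    missing: list[str] = []
    for f in FEATURES:
        v = fv.value(f)
        if v is None:
            missing.append(f)
            continue
        dens = lookup_npdf(db, fv.residue_type, f, v)
        score = hbos_component(dens, params)
        setattr(comps, f, score)
        comps.floor_applied[f] = dens < params.npdf_floor
    if missing:
        total: float | None = None
        is_outlier = False
    else:
        total = float(sum(comps.value(f) for f in FEATURES))
        is_outlier = total > params.outlier_threshold
    flagged = tuple(
        f for f in FEATURES
        if comps.value(f) is not None and comps.value(f) > params.flag_threshold
    )
    return ResidueScore(
        residue_type=fv.residue_type,
        residue_index=fv.residue_index,
        icode=fv.icode,
        chain_id=fv.chain_id,
        components=comps,
        total=total,
        is_outlier=is_outlier,
        flagged_features=flagged,
        missing_features=tuple(missing),
    )


def score_chain(
    chain: Chain,
    db: ReferenceDB,
    params: ScoringParams = ScoringParams(),
    blocks: dict[str, BlockDefinition] | None = None,
) -> list[ResidueScore]:
    """Score every scoreable residue of a chain, preserving order.

    Residues with missing features appear in the output unscored, with the
    missing features recorded as the reason.
    """
    if blocks is None:
        blocks = load_blocks()
    return [score_residue(fv, db, params) for fv in extract_features(chain, blocks)]


def hbos_distribution(
    scores: list[ResidueScore], bin_width: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Probability distribution of residue totals over fixed-width bins.

    Returns (edges, mass): ``mass[i]`` is the fraction of scored residues
    whose total falls in ``[edges[i], edges[i+1])``; the masses sum to 1.
    Used for threshold-calibration plots of the score distribution.
    """
    totals = np.array([s.total for s in scores if s.scored])
    if totals.size == 0:
        raise ValueError("hbos_distribution requires at least one scored residue")
    n_bins = int(math.floor(totals.max() / bin_width)) + 1
    edges = bin_width * np.arange(n_bins + 1)
    idx = np.minimum((totals / bin_width).astype(int), n_bins - 1)
    mass = np.bincount(idx, minlength=n_bins).astype(float) / totals.size
    return edges, mass
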