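"""The reference database of peak-normalized histogram densities (npdfs).

For each of the 18 scoreable residue types and each of the 5 features, a
histogram is accumulated over a reference corpus (high-resolution structures
or synthetic peptides), then rescaled so its highest bin equals 1. Torsions
use 5-degree bins over [0, 360); distances use 0.05 Å bins from 0 to a
configurable cap (default 10 Å). 18 x 5 = 90 tables make a complete database.
"""

from __future__ import annotations

import datetime
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .chemistry import SCOREABLE_TYPES, load_blocks
from .features import FEATURES, FeatureVector, extract_features
from .structure_io import deduplicate_chains, parse_structure

__all__ = [
    "ANGLE_FEATURES", "DISTANCE_FEATURES", "OUT_OF_RANGE",
    "BinSpec", "NpdfTable", "ReferenceDB", "ReferenceParams",
    "bin_index", "accumulate", "normalize_to_peak", "lookup_npdf",
    "save_db", "load_db", "build_reference", "SCHEMA_VERSION",
]

ANGLE_FEATURES = ("phi", "psi", "chi1")
DISTANCE_FEATURES = ("d_sidechain", "d_block")

#: Sentinel returned by bin_index for a distance beyond the domain cap.
OUT_OF_RANGE = None

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class BinSpec:
    """Uniform half-open bins [lower, upper) of equal width."""

    lower: float
    upper: float
    width: float
    periodic: bool = False  # angles wrap at the upper edge

    def __post_init__(self) -> None:
        if self.width <= 0 or self.upper <= self.lower:
            raise ValueError("BinSpec requires width > 0 and upper > lower")
        n = (self.upper - self.lower) / self.width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("bin width must divide the domain exactly")

    @property
    def count(self) -> int:
        return round((self.upper - self.lower) / self.width)

    def edges(self) -> np.ndarray:
        return self.lower + self.width * np.arange(self.count + 1)


def angle_bins(width: float = 5.0) -> BinSpec:
    return BinSpec(0.0, 360.0, width, periodic=True)


def distance_bins(width: float = 0.05, cap: float = 10.0) -> BinSpec:
    return BinSpec(0.0, cap, width, periodic=False)


def bin_index(value: float, bins: BinSpec) -> int | None:
    """Half-open bin index of a value, or OUT_OF_RANGE (None).

    Angles are wrapped into [lower, upper) first, so 360 maps to bin 0.
    Distances below lower or at/above upper are OUT_OF_RANGE.
    """
    if bins.periodic:
        span = bins.upper - bins.lower
        value = bins.lower + (value - bins.lower) % span
    elif value < bins.lower or value >= bins.upper:
        return OUT_OF_RANGE
    idx = int(math.floor((value - bins.lower) / bins.width))
    return min(idx, bins.count - 1)


def normalize_to_peak(counts: Sequence[float] | np.ndarray) -> np.ndarray:
    """Rescale a count vector by its maximum; an all-zero vector stays zero."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative histogram counts")
    peak = counts.max() if counts.size else 0.0
    if peak == 0.0:
        return np.zeros_like(counts)
    return counts / peak


@dataclass
class NpdfTable:
    """Peak-normalized histogram density for one (residue type, feature)."""

    residue_type: str
    feature: str
    bins: BinSpec
    density: np.ndarray
    sample_count: int

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if self.density.shape != (self.bins.count,):
            raise ValueError(
                f"{self.residue_type}/{self.feature}: density length "
                f"{self.density.shape} != bin count {self.bins.count}"
            )
        if np.any((self.density < 0) | (self.density > 1)):
            raise ValueError(f"{self.residue_type}/{self.feature}: density outside [0,1]")
        if self.sample_count > 0 and not math.isclose(self.density.max(), 1.0):
            raise ValueError(
                f"{self.residue_type}/{self.feature}: non-empty table must peak at 1"
            )


@dataclass
class ReferenceDB:
    """The complete 90-table database plus build provenance."""

    tables: dict[tuple[str, str], NpdfTable]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = {(t, f) for t in SCOREABLE_TYPES for f in FEATURES}
        missing = expected - set(self.tables)
        extra = set(self.tables) - expected
        if missing or extra:
            raise ValueError(
                f"reference DB must hold exactly the {len(expected)} "
                f"(type, feature) tables; missing={sorted(missing)} extra={sorted(extra)}"
            )

    def table(self, residue_type: str, feature: str) -> NpdfTable:
        key = (residue_type, feature)
        if key not in self.tables:
            raise KeyError(f"no npdf table for {key}")
        return self.tables[key]


def lookup_npdf(db: ReferenceDB, residue_type: str, feature: str, value: float) -> float:
    """Density in [0, 1] read from the npdf of (residue_type, feature).

    A distance beyond the table's domain cap reads as 0 (never observed).
    """
    table = db.table(residue_type, feature)
    idx = bin_index(value, table.bins)
    if idx is OUT_OF_RANGE:
        return 0.0
    return float(table.density[idx])


@dataclass(frozen=True)
class ReferenceParams:
    """Histogram and deduplication settings for building a reference DB."""

    angle_bin_width: float = 5.0
    distance_bin_width: float = 0.05
    distance_cap: float = 10.0
    dedup: bool = True
    dedup_threshold: float = 0.95

    def bins_for(self, feature: str) -> BinSpec:
        if feature in ANGLE_FEATURES:
            return angle_bins(self.angle_bin_width)
        return distance_bins(self.distance_bin_width, self.distance_cap)


class HistogramBuilder:
    """Mutable count accumulator for the 90 (type, feature) histograms."""

    def __init__(self, params: ReferenceParams | None = None) -> None:
        self.params = params or ReferenceParams()
        self.counts: dict[tuple[str, str], np.ndarray] = {}
        for t in SCOREABLE_TYPES:
            for f in FEATURES:
                self.counts[(t, f)] = np.zeros(self.params.bins_for(f).count)
        self.n_observations = 0

    def add(self, fv: FeatureVector) -> None:
        if fv.residue_type not in SCOREABLE_TYPES:
            return
        for f in FEATURES:
            v = fv.value(f)
            if v is None:
                continue
            idx = bin_index(v, self.params.bins_for(f))
            if idx is OUT_OF_RANGE:
                continue
            self.counts[(fv.residue_type, f)][idx] += 1
            self.n_observations += 1

    def finalize(self, metadata: dict | None = None) -> ReferenceDB:
        tables = {}
        for (t, f), counts in self.counts.items():
            tables[(t, f)] = NpdfTable(
                residue_type=t,
                feature=f,
                bins=self.params.bins_for(f),
                density=normalize_to_peak(counts),
                sample_count=int(counts.sum()),
            )
        meta = {
            "angle_bin_width": self.params.angle_bin_width,
            "distance_bin_width": self.params.distance_bin_width,
            "distance_cap": self.params.distance_cap,
            "dedup_threshold": self.params.dedup_threshold if self.params.dedup else None,
        }
        meta.update(metadata or {})
        return ReferenceDB(tables=tables, metadata=meta)


def accumulate(features: Iterable[FeatureVector], builder: HistogramBuilder) -> HistogramBuilder:
    """Add each non-missing feature value to its (type, feature) histogram."""
    for fv in features:
        builder.add(fv)
    return builder


def build_reference(
    paths: Sequence[str | Path],
    params: ReferenceParams | None = None,
    blocks=None,
    on_error: str = "raise",
) -> ReferenceDB:
    """Build a ReferenceDB from coordinate files.

    Pipeline per file: parse, drop near-duplicate chains, extract features,
    accumulate. ``on_error="warn"`` logs unreadable files and continues.
    """
    import logging

    if not paths:
        raise ValueError("build_reference needs at least one input file")
    params = params or ReferenceParams()
    if blocks is None:
        blocks = load_blocks()
    builder = HistogramBuilder(params)
    log = logging.getLogger(__name__)
    n_files = 0
    n_residues = 0
    for p in paths:
        try:
            st = parse_structure(p)
        except Exception as exc:
            if on_error == "warn":
                log.warning("skipping %s: %s", p, exc)
                continue
            raise
        chains = deduplicate_chains(st, params.dedup_threshold) if params.dedup else st.chains
        for chain in chains:
            fvs = extract_features(chain, blocks)
            accumulate(fvs, builder)
            n_residues += len(fvs)
        n_files += 1
    if builder.n_observations == 0:
        raise ValueError("empty corpus: no scoreable residues in the inputs")
    return builder.finalize(
        {
            "n_files": n_files,
            "n_residues": n_residues,
            "built": datetime.date.today().isoformat(),
        }
    )


def save_db(db: ReferenceDB, path: str | Path) -> None:
    """Write a ReferenceDB to a JSON file (schema-versioned, full precision)."""
    doc = {
        "version": SCHEMA_VERSION,
        "metadata": db.metadata,
        "tables": [
            {
                "residue_type": t.residue_type,
                "feature": t.feature,
                "lower": t.bins.lower,
                "upper": t.bins.upper,
                "width": t.bins.width,
                "periodic": t.bins.periodic,
                "sample_count": t.sample_count,
                "density": t.density.tolist(),
            }
            for t in db.tables.values()
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_db(path: str | Path) -> ReferenceDB:
    """Load a ReferenceDB; rejects wrong schema versions and incomplete DBs."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not a valid reference DB (JSON error: {exc})") from exc
    if not isinstance(doc, dict) or "version" not in doc:
        raise ValueError(f"{path}: not a reference DB file (no schema version)")
    if doc["version"] != SCHEMA_VERSION:
        raise ValueError(
            f"{path}: schema version {doc['version']} unsupported "
            f"(expected {SCHEMA_VERSION})"
        )
    tables = {}
    for rec in doc["tables"]:
        t = NpdfTable(
            residue_type=rec["residue_type"],
            feature=rec["feature"],
            bins=BinSpec(rec["lower"], rec["upper"], rec["width"],
                         periodic=rec.get("periodic", rec["feature"] in ANGLE_FEATURES)),
            density=np.array(rec["density"]),
            sample_count=rec["sample_count"],
        )
        tables[(t.residue_type, t.feature)] = t
    return ReferenceDB(tables=tables, metadata=doc.get("metadata", {}))
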