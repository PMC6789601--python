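"""Report writers: tabular outlier reports and attribute files for coloring.

Column names follow the validation-report convention: B-Dist and S-Dist are
the block-length and side-chain-size components, Phi/Psi/Chi_1 the torsion
components. TSV rounds scores to two decimals for reading; JSON carries full
precision. The Chimera attribute file maps residue specifiers to total HBOS
so any visualization platform can color residues by score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .scoring import ResidueScore

__all__ = [
    "OutlierReport", "build_report", "write_tsv", "write_json",
    "write_chimera_attributes", "read_chimera_attributes",
]

#: Report column -> (feature name, description)
COLUMN_FEATURES = {
    "B-Dist": "d_block",
    "S-Dist": "d_sidechain",
    "Phi": "phi",
    "Psi": "psi",
    "Chi_1": "chi1",
}
COLUMNS = ["Residue", "Index", "B-Dist", "S-Dist", "Phi", "Psi", "Chi_1",
           "Total", "Outlier", "Flagged"]


@dataclass
class OutlierReport:
    """Scored residues of one chain plus the run's provenance header."""

    scores: list[ResidueScore]
    metadata: dict = field(default_factory=dict)
    mode: str = "outliers"  # "outliers" or "full"

    def rows(self) -> list[dict]:
        out = []
        for s in self.scores:
            if self.mode == "outliers" and not s.is_outlier:
                continue
            row: dict = {"Residue": s.residue_type, "Index": s.label}
            for col, feat in COLUMN_FEATURES.items():
                row[col] = s.components.value(feat)
            row["Total"] = s.total
            row["Outlier"] = s.is_outlier
            # features whose individual score exceeds the flag threshold
            row["Flagged"] = ",".join(
                col for col, feat in COLUMN_FEATURES.items()
                if feat in s.flagged_features
            )
            if not s.scored:
                row["Flagged"] = "unscored:" + ",".join(s.missing_features)
            out.append(row)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows(), columns=COLUMNS)


def build_report(scores: list[ResidueScore], mode: str = "outliers",
                 metadata: dict | None = None) -> OutlierReport:
    if mode not in ("outliers", "full"):
        raise ValueError(f"unknown report mode {mode!r}")
    return OutlierReport(scores=scores, metadata=metadata or {}, mode=mode)


def write_tsv(report: OutlierReport, path: str | Path) -> Path:
    """Write the report as TSV with a commented provenance header."""
    p = Path(path)
    header = "".join(f"# {k}: {v}\n" for k, v in report.metadata.items())
    df = report.to_frame()
    for col in ("B-Dist", "S-Dist", "Phi", "Psi", "Chi_1", "Total"):
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
    p.write_text(header + df.to_csv(sep="\t", index=False))
    return p


def write_json(report: OutlierReport, path: str | Path) -> Path:
    """Write the report as JSON (full numeric precision)."""
    doc = {"metadata": report.metadata, "rows": report.rows()}
    Path(path).write_text(json.dumps(doc, indent=1))
    return Path(path)


def write_chimera_attributes(scores: list[ResidueScore], path: str | Path,
                             attr_name: str = "hbosScore") -> Path:
    """Write a Chimera-style residue attribute file of total HBOS values.

    One line per scored residue: ``<TAB>:<index>.<chain><TAB><total>``.
    Unscored residues are omitted.
    """
    lines = [
        f"attribute: {attr_name}",
        "match mode: 1-to-1",
        "recipient: residues",
    ]
    for s in scores:
        if not s.scored:
            continue
        lines.append(f"\t:{s.label}.{s.chain_id}\t{s.total:.6f}")
    p = Path(path)
    p.write_text("\n".join(lines) + "\n")
    return p


def read_chimera_attributes(path: str | Path) -> dict[str, float]:
    """Parse an attribute file back into {residue specifier: value}."""
    out: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        if not line.startswith("\t"):
            continue
        spec_str, value = line.strip().split("\t")
        out[spec_str] = float(value)
    return out
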