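"""Aggregate statistics over a profile table.

Summaries mirror how this class of analysis is reported: per-cluster counts
and percentages of the total, the pocket-candidate count as a percentage of
the outer-layer cluster, per-cluster V/v moments, and amino-acid composition
matrices (wild-type and mutant, percent within each cluster). Percentages
are rounded half-away-from-zero to one decimal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .dataset import STATUS_PROFILED

CLUSTERS = (1, 2, 3)


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed percentages)."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class ClusterSummary:
    """Aggregate statistics of a profiled mutation-site table."""

    counts: dict[int, int]
    percentages: dict[int, float]
    pocket_count: int
    pocket_pct: float  # % of cluster 2
    v_ratio_mean: dict[int, float] = field(default_factory=dict)
    v_ratio_std: dict[int, float] = field(default_factory=dict)
    wild_composition: pd.DataFrame | None = None   # % within cluster
    mutant_composition: pd.DataFrame | None = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_dict(self) -> dict:
        out = {
            "total": self.total,
            "counts": {str(k): v for k, v in sorted(self.counts.items())},
            "percentages": {str(k): v for k, v in sorted(self.percentages.items())},
            "pocket_count": self.pocket_count,
            "pocket_pct_of_cluster2": self.pocket_pct,
            "v_ratio_mean": {str(k): v for k, v in sorted(self.v_ratio_mean.items())},
            "v_ratio_std": {str(k): v for k, v in sorted(self.v_ratio_std.items())},
        }
        if self.wild_composition is not None:
            out["wild_composition_pct"] = {
                str(c): self.wild_composition.loc[c].dropna().to_dict()
                for c in self.wild_composition.index
            }
        if self.mutant_composition is not None:
            out["mutant_composition_pct"] = {
                str(c): self.mutant_composition.loc[c].dropna().to_dict()
                for c in self.mutant_composition.index
            }
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = [f"profiled sites: {self.total}"]
        for c in CLUSTERS:
            lines.append(
                f"  cluster {c}: {self.counts.get(c, 0)} ({self.percentages.get(c, 0.0)}%)"
            )
        lines.append(
            f"  pocket candidates: {self.pocket_count} "
            f"({self.pocket_pct}% of cluster 2)"
        )
        return "\n".join(lines)


def summarize_counts(counts: dict[int, int], pocket_count: int) -> ClusterSummary:
    """Summary from bare per-cluster counts and a pocket-candidate count."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no profiled sites to summarize")
    percentages = {
        c: round_half_away(100.0 * counts.get(c, 0) / total) for c in CLUSTERS
    }
    n2 = counts.get(2, 0)
    pocket_pct = round_half_away(100.0 * pocket_count / n2) if n2 else 0.0
    return ClusterSummary(
        counts={c: counts.get(c, 0) for c in CLUSTERS},
        percentages=percentages,
        pocket_count=pocket_count,
        pocket_pct=pocket_pct,
    )


def _composition(profiled: pd.DataFrame, aa_of_row) -> pd.DataFrame:
    rows = {}
    for c in CLUSTERS:
        sub = profiled[profiled["cluster"] == c]
        if len(sub) == 0:
            rows[c] = {}
            continue
        freq = aa_of_row(sub).value_counts()
        rows[c] = {
            aa: round_half_away(100.0 * n / len(sub)) for aa, n in freq.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def summarize_clusters(table: pd.DataFrame) -> ClusterSummary:
    """Summary of a profile table (only rows with status ``profiled`` count)."""
    profiled = table[table["status"] == STATUS_PROFILED]
    if len(profiled) == 0:
        raise ValueError("profile table contains no profiled rows")
    counts = {c: int((profiled["cluster"] == c).sum()) for c in CLUSTERS}
    pocket_count = int(
        sum(bool(v) for v in profiled["pocket_candidate"] if pd.notna(v))
    )
    summary = summarize_counts(counts, pocket_count)

    for c in CLUSTERS:
        vr = profiled.loc[profiled["cluster"] == c, "v_ratio"].astype(float)
        if len(vr):
            summary.v_ratio_mean[c] = float(np.mean(vr))
            summary.v_ratio_std[c] = float(np.std(vr, ddof=1)) if len(vr) > 1 else 0.0

    wild = lambda sub: sub["mutation"].str[:3].str.upper()
    mutant = lambda sub: sub["mutation"].str[-3:].str.upper()
    summary.wild_composition = _composition(profiled, wild)
    summary.mutant_composition = _composition(profiled, mutant)
    return summary
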