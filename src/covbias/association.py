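"""Statistical comparisons between coverage metrics and sequence features.

Extreme-transcript set construction, the unpaired Wilcoxon rank-sum
(Mann-Whitney U) test, per-transcript effect-size ratios against simulated
data, and Pearson R^2 correlation summaries. No multiple-testing correction
is applied; raw p-values are emitted together so users may adjust.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExtremeSets",
    "extreme_sets",
    "rank_sum_test",
    "effect_size_ratios",
    "pearson_r2",
    "association_report",
]


@dataclass
class ExtremeSets:
    """The n least / n most extreme transcripts by one metric in one library."""

    metric: str
    library: str
    low: list[str]
    high: list[str]

    def __post_init__(self) -> None:
        if set(self.low) & set(self.high):
            raise ValueError("low and high sets must be disjoint")


def extreme_sets(
    metrics: pd.DataFrame,
    metric: str,
    library: str = "",
    fpkm_min: float = 5.0,
    n: int = 100,
) -> ExtremeSets:
    """Select the ``n`` least and most extreme transcripts by a metric.

    Transcripts with FPKM <= ``fpkm_min`` are excluded first; the survivors
    are sorted ascending by the metric with ties broken by transcript id,
    and the first / last ``n`` form the low / high sets. Raises when fewer
    than 2n transcripts survive the filter.
    """
    required = {"transcript_id", "fpkm", metric}
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table missing columns: {sorted(missing)}")
    surv = metrics[(metrics["fpkm"] > fpkm_min) & metrics[metric].notna()]
    if len(surv) < 2 * n:
        raise ValueError(
            f"need >= {2 * n} transcripts above the FPKM filter, have {len(surv)}"
        )
    surv = surv.sort_values([metric, "transcript_id"], kind="stable")
    ids = surv["transcript_id"].tolist()
    return ExtremeSets(metric, library, ids[:n], ids[-n:])


def rank_sum_test(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (Wilcoxon rank-sum) test.

    Exact null distribution when n + m <= 12 and the pooled sample is
    tie-free; otherwise the normal approximation with midrank ties and
    continuity correction. Returns (U statistic for x, two-sided p).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if x.size + y.size <= 12 and tie_free:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def effect_size_ratios(
    lib_cv: Mapping[str, float] | pd.Series,
    sim_cv: Mapping[str, float] | pd.Series,
) -> tuple[pd.Series, dict[str, float]]:
    """Per-transcript CV ratios of a library against the simulated dataset.

    Returns the ratios over shared transcripts (simulated CV must be
    positive) and a summary with the mean, median and quartiles.
    """
    lib = pd.Series(dict(lib_cv), dtype=float).dropna()
    sim = pd.Series(dict(sim_cv), dtype=float).dropna()
    sim = sim[sim > 0]
    shared = lib.index.intersection(sim.index)
    if shared.empty:
        raise ValueError("no shared transcripts between library and simulation")
    ratios = (lib.loc[shared] / sim.loc[shared]).sort_index()
    summary = {
        "mean": float(ratios.mean()),
        "median": float(ratios.median()),
        "q25": float(ratios.quantile(0.25)),
        "q75": float(ratios.quantile(0.75)),
        "n": int(len(ratios)),
    }
    return ratios, summary


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation; NaN for constant input or < 3 pairs."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def association_report(
    metrics: pd.DataFrame,
    features: pd.DataFrame,
    metric_cols: Sequence[str] = ("base_cv", "fpkm"),
    feature_cols: Sequence[str] = ("hexamer_entropy", "gc_fraction", "rrna_score"),
    library: str = "",
    fpkm_min: float = 5.0,
    n: int = 100,
) -> pd.DataFrame:
    """Rank-sum comparisons of sequence features between extreme transcript sets.

    For each metric, builds the low/high extreme sets and tests every
    feature between them. Returns a tidy report: metric, feature, group
    medians, U statistic, two-sided p, and the direction of the effect
    (sign of high-set median minus low-set median).
    """
    feat = features.set_index("transcript_id")
    rows = []
    for metric in metric_cols:
        sets = extreme_sets(metrics, metric, library, fpkm_min, n)
        for feature in feature_cols:
            low_vals = feat.loc[[t for t in sets.low if t in feat.index], feature].dropna()
            high_vals = feat.loc[[t for t in sets.high if t in feat.index], feature].dropna()
            stat, p = rank_sum_test(low_vals.to_numpy(), high_vals.to_numpy())
            med_low, med_high = float(low_vals.median()), float(high_vals.median())
            rows.append(
                {
                    "library": library,
                    "metric": metric,
                    "feature": feature,
                    "median_low": med_low,
                    "median_high": med_high,
                    "statistic": stat,
                    "p_value": p,
                    "direction": int(np.sign(med_high - med_low)),
                }
            )
    return pd.DataFrame(rows)
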