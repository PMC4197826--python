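"""Per-transcript coverage statistics.

FPKM, detection counts, base-level coefficient of variation, the
within-transcript fold-change statistic (90th-decile mean over 10th-decile
mean of per-base depths after end trimming), the 3'/5' processivity ratio,
and read-end nucleotide frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import FpkmTable, TranscriptCoverage

__all__ = [
    "MetricsConfig",
    "compute_fpkm",
    "detect_expressed",
    "base_cv",
    "within_transcript_fold_change",
    "fold_change_summary",
    "processivity_ratio",
    "read_end_nt_frequencies",
    "metrics_table",
]

#: Sentinel reason strings for excluded transcripts.
EXCLUDED_SHORT = "length_below_minimum"
EXCLUDED_FPKM = "fpkm_at_or_below_minimum"
EXCLUDED_ZERO = "zero_coverage"


@dataclass
class MetricsConfig:
    """Thresholds for the coverage statistics.

    Defaults follow the operational choices of the source study: detection at
    FPKM >= 5, a 200-base end trim with a 500-base minimum length for the
    fold-change statistic, decile bins at the 10th/90th percentiles, nested
    fold-change thresholds (2, 10, 100), and fractional 5'/3' processivity
    windows 5-15% / 85-95% with an FPKM > 5 inclusion rule.
    """

    fpkm_detect_threshold: float = 5.0
    fc_trim: int = 200
    fc_min_length: int = 500
    fc_low_pct: float = 10.0
    fc_high_pct: float = 90.0
    fc_thresholds: tuple[float, ...] = (2.0, 10.0, 100.0)
    fc_mode: str = "decile_bin"  # or "cutoff": mean of values <=/>= percentile cuts
    proc_5p_window: tuple[float, float] = (0.05, 0.15)
    proc_3p_window: tuple[float, float] = (0.85, 0.95)
    proc_min_fpkm: float = 5.0

    def __post_init__(self) -> None:
        if not (0 < self.fc_low_pct < self.fc_high_pct < 100):
            raise ValueError("need 0 < fc_low_pct < fc_high_pct < 100")
        if self.fc_trim < 0:
            raise ValueError("fc_trim must be >= 0")
        for lo, hi in (self.proc_5p_window, self.proc_3p_window):
            if not (0 < lo < hi < 1):
                raise ValueError("processivity windows must lie within (0, 1)")
        if self.proc_5p_window[1] > self.proc_3p_window[0]:
            raise ValueError("processivity windows must not overlap")
        if self.fc_mode not in ("decile_bin", "cutoff"):
            raise ValueError("fc_mode must be 'decile_bin' or 'cutoff'")


def compute_fpkm(
    fragment_count: float, length: int, total_mapped_fragments: float
) -> float:
    """Fragments per kilobase of exon per million mapped fragments."""
    if length <= 0:
        raise ValueError("transcript length must be >= 1")
    if total_mapped_fragments <= 0:
        raise ValueError("total mapped fragments must be >= 1")
    return fragment_count / ((length / 1e3) * (total_mapped_fragments / 1e6))


def detect_expressed(table: FpkmTable, threshold: float = 5.0) -> dict[str, int]:
    """Per-sample count of transcripts with FPKM >= threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out: dict[str, int] = {}
    for sample in table.samples:
        values = table.sample_values(sample)
        out[sample] = int((values >= threshold).sum())
    return out


def base_cv(cov: TranscriptCoverage) -> float:
    """Coefficient of variation of per-base depths (sample sd / mean).

    Returns NaN for all-zero coverage (undefined; excluded downstream).
    """
    depths = cov.depths
    mean = depths.mean() if len(depths) else 0.0
    if mean == 0:
        return math.nan
    return float(depths.std(ddof=1) / mean)


def _decile_bin_means(depths: np.ndarray, low_pct: float, high_pct: float,
                      mode: str) -> tuple[float, float]:
    """Bottom/top percentile-bin means of sorted per-base depths.

    decile_bin: mean of the lowest and highest floor(n * pct/100) bases
    (ties broken by position through the stable sort). cutoff: mean of values
    at or below / at or above the interpolated percentile cut.
    """
    srt = np.sort(depths, kind="stable")
    n = len(srt)
    if mode == "decile_bin":
        k_low = max(int(n * low_pct / 100), 1)
        k_high = max(int(n * (100 - high_pct) / 100), 1)
        return float(srt[:k_low].mean()), float(srt[-k_high:].mean())
    lo_cut = np.percentile(srt, low_pct)
    hi_cut = np.percentile(srt, high_pct)
    return float(srt[srt <= lo_cut].mean()), float(srt[srt >= hi_cut].mean())


def within_transcript_fold_change(
    cov: TranscriptCoverage, cfg: MetricsConfig | None = None
) -> float | str:
    """Within-transcript coverage fold change: top-decile mean / bottom-decile mean.

    The first and last ``fc_trim`` bases are trimmed; transcripts shorter
    than ``fc_min_length`` are excluded (returned as a reason string). A
    bottom-decile mean of zero yields ``inf``.
    """
    cfg = cfg or MetricsConfig()
    if len(cov) < cfg.fc_min_length:
        return EXCLUDED_SHORT
    depths = cov.depths[cfg.fc_trim : len(cov.depths) - cfg.fc_trim]
    if len(depths) == 0:
        return EXCLUDED_SHORT
    bottom, top = _decile_bin_means(depths, cfg.fc_low_pct, cfg.fc_high_pct, cfg.fc_mode)
    if bottom == 0:
        return math.inf
    return top / bottom


def fold_change_summary(
    values: Iterable[float], thresholds: Sequence[float] = (2.0, 10.0, 100.0)
) -> tuple[int, ...]:
    """Strictly-greater-than counts at each (ascending, nested) threshold.

    A transcript above the highest threshold is counted at every lower one;
    infinities count in every bucket. Non-numeric (excluded) entries are
    ignored.
    """
    thresholds = tuple(thresholds)
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    numeric = [v for v in values if isinstance(v, (int, float)) and not math.isnan(v)]
    return tuple(sum(1 for v in numeric if v > t) for t in thresholds)


def processivity_ratio(
    cov: TranscriptCoverage,
    fpkm: float | None = None,
    cfg: MetricsConfig | None = None,
) -> float | str:
    """3'/5' coverage ratio over fractional windows (default 85-95% / 5-15%).

    Window bounds are floor(L * fraction), half-open, so a 1,000-base
    transcript uses [50, 150) and [850, 950). Transcripts with
    fpkm <= proc_min_fpkm are excluded; a zero 5' mean yields NaN.
    """
    cfg = cfg or MetricsConfig()
    if fpkm is not None and fpkm <= cfg.proc_min_fpkm:
        return EXCLUDED_FPKM
    n = len(cov)
    lo5 = int(n * cfg.proc_5p_window[0])
    hi5 = int(n * cfg.proc_5p_window[1])
    lo3 = int(n * cfg.proc_3p_window[0])
    hi3 = int(n * cfg.proc_3p_window[1])
    if hi5 <= lo5 or hi3 <= lo3:
        return EXCLUDED_SHORT
    mean5 = cov.depths[lo5:hi5].mean()
    mean3 = cov.depths[lo3:hi3].mean()
    if mean5 == 0:
        return math.nan
    return float(mean3 / mean5)


def read_end_nt_frequencies(read_prefixes: Sequence[str]) -> pd.DataFrame:
    """Position x base frequency matrix over fixed-length 5' read prefixes.

    N bases are excluded from the denominator; each row sums to 1 wherever
    any non-N base was observed.
    """
    if not read_prefixes:
        raise ValueError("no reads supplied")
    length = len(read_prefixes[0])
    if any(len(r) != length for r in read_prefixes):
        raise ValueError("all read prefixes must have equal length")
    bases = "ACGT"
    counts = np.zeros((length, 4), dtype=np.int64)
    arr = np.frombuffer("".join(r.upper() for r in read_prefixes).encode(),
                        dtype="S1").reshape(len(read_prefixes), length)
    for j, b in enumerate(bases):
        counts[:, j] = (arr == b.encode()).sum(axis=0)
    bad = ~np.isin(arr, [b.encode() for b in "ACGTN"])
    if bad.any():
        raise ValueError("read prefixes contain bases outside {A,C,G,T,N}")
    totals = counts.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / totals, 0.0)
    return pd.DataFrame(freqs, columns=list(bases))


def metrics_table(
    coverages: Mapping[str, TranscriptCoverage],
    fpkm: Mapping[str, float],
    sample: str,
    cfg: MetricsConfig | None = None,
) -> pd.DataFrame:
    """Per-transcript metrics for one sample as a tidy DataFrame.

    Columns: transcript_id, length, sample, fpkm, base_cv, fold_change,
    processivity, excluded_reason. Numeric columns are NaN where undefined;
    excluded_reason records why a statistic was withheld.
    """
    cfg = cfg or MetricsConfig()
    rows = []
    for tid in sorted(coverages):
        cov = coverages[tid]
        f = float(fpkm.get(tid, 0.0))
        fc = within_transcript_fold_change(cov, cfg)
        proc = processivity_ratio(cov, f, cfg)
        reasons = []
        if isinstance(fc, str):
            reasons.append(f"fold_change:{fc}")
            fc_val = math.nan
        else:
            fc_val = fc
        if isinstance(proc, str):
            reasons.append(f"processivity:{proc}")
            proc_val = math.nan
        else:
            proc_val = proc
        rows.append(
            {
                "transcript_id": tid,
                "length": len(cov),
                "sample": sample,
                "fpkm": f,
                "base_cv": base_cv(cov),
                "fold_change": fc_val,
                "processivity": proc_val,
                "excluded_reason": ";".join(reasons),
            }
        )
    return pd.DataFrame(rows)
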