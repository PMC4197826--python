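"""Detection of high, unpredictable coverage (hunc) regions.

A hunc region is a transcript interval whose read depth varies extremely
across the dilution-series conditions relative to the rest of the
transcript, reproducibly in both replicates. The caller:

1. min-max normalizes each condition's coverage vector to [0, 1] per
   transcript (a constant vector maps to all zeros);
2. takes the per-base median absolute deviation (MAD, scale constant 1)
   across the five conditions;
3. smooths with a 100-base sliding window centred on each base (full
   windows only) and trims the first 300 / last 250 window scores;
4. thresholds at the pooled 95th-percentile score per replicate, keeps runs
   of >= 20 contiguous above-cutoff windows, intersects candidate intervals
   across replicates, and applies mouse-background filters (transcript-level
   mouse-only FPKM, and local mouse-only coverage in the region and its
   100-bp flanks).

Replicate-divergent regions are found from the per-window replicate score
difference thresholded at its pooled 2.5th/97.5th percentiles, with the
same mouse filters plus an exclusion zone around already-called huncs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .models import DilutionSeries

__all__ = [
    "HuncConfig",
    "HuncRegion",
    "HuncResult",
    "WindowScores",
    "mad_constant1",
    "windowed_mad_scores",
    "score_series",
    "call_hunc_regions",
    "difference_regions",
]


@dataclass
class HuncConfig:
    """Thresholds of the hunc-calling procedure (defaults from the source study)."""

    window: int = 100
    trim_head: int = 300
    trim_tail: int = 250
    mad_quantile: float = 0.95
    min_contiguous: int = 20
    diff_quantiles: tuple[float, float] = (0.025, 0.975)
    mouse_fpkm_max: float = 5.0
    mouse_cov_max: float = 10.0
    flank: int = 100
    hunc_exclusion_distance: int = 200
    # numerical guard: per-base MADs below this are floating-point residue of
    # exactly proportional coverage vectors and are treated as zero
    mad_floor: float = 1e-12

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if not (0 < self.mad_quantile < 1):
            raise ValueError("mad_quantile must be in (0, 1)")
        lo, hi = self.diff_quantiles
        if not (0 < lo < hi < 1):
            raise ValueError("diff_quantiles must satisfy 0 < low < high < 1")
        if self.min_contiguous < 1:
            raise ValueError("min_contiguous must be >= 1")


@dataclass
class HuncRegion:
    """A called interval in transcript space with its score and provenance."""

    transcript_id: str
    start: int
    end: int
    mean_mad: float
    replicate_support: bool = True
    status: str = "passed"
    source: str = "hunc"  # or "difference"
    direction: int = 0  # sign of the replicate difference for difference regions

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.transcript_id}: empty region")

    @property
    def passed(self) -> bool:
        return self.status == "passed"


@dataclass
class WindowScores:
    """Retained windowed MAD scores for one transcript of one replicate."""

    transcript_id: str
    centers: np.ndarray  # window-centre base coordinates, consecutive ints
    scores: np.ndarray
    transcript_length: int


@dataclass
class HuncResult:
    """Output bundle of a calling run: survivors, rejections, and cutoffs."""

    regions: list[HuncRegion]
    rejected: list[HuncRegion]
    cutoffs: tuple[float, ...]


def mad_constant1(values: Sequence[float] | np.ndarray) -> float:
    """Median absolute deviation with scale constant 1: median(|x - median(x)|)."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("MAD of an empty vector is undefined")
    return float(np.median(np.abs(arr - np.median(arr))))


def _minmax_rows(matrix: np.ndarray) -> np.ndarray:
    """Min-max normalize each row to [0, 1]; constant rows map to all zeros."""
    mins = matrix.min(axis=1, keepdims=True)
    ranges = matrix.max(axis=1, keepdims=True) - mins
    out = np.zeros_like(matrix, dtype=np.float64)
    nonconst = ranges[:, 0] > 0
    out[nonconst] = (matrix[nonconst] - mins[nonconst]) / ranges[nonconst]
    return out


def windowed_mad_scores(
    series: DilutionSeries, transcript_id: str, cfg: HuncConfig | None = None
) -> WindowScores:
    """Trimmed sliding-window mean of per-base across-condition MADs.

    The window centred on base ``i`` covers ``[i - w//2, i + w//2)``; only
    full windows are scored, so centres run over ``range(w//2, L - w//2)``.
    The first ``trim_head`` and last ``trim_tail`` scored windows are then
    dropped. Raises ``ValueError`` when the transcript is too short to
    retain any window.
    """
    cfg = cfg or HuncConfig()
    matrix = series.matrix(transcript_id)
    length = matrix.shape[1]
    half = cfg.window // 2
    n_windows = length - cfg.window
    if n_windows - cfg.trim_head - cfg.trim_tail <= 0:
        raise ValueError(
            f"{transcript_id}: length {length} leaves no scored windows after "
            f"trimming {cfg.trim_head}+{cfg.trim_tail} of {max(n_windows, 0)}"
        )
    norm = _minmax_rows(matrix)
    per_base_mad = np.median(
        np.abs(norm - np.median(norm, axis=0, keepdims=True)), axis=0
    )
    per_base_mad[per_base_mad < cfg.mad_floor] = 0.0
    kernel = np.full(cfg.window, 1.0 / cfg.window)
    means = np.convolve(per_base_mad, kernel, mode="valid")[:n_windows]
    centers = np.arange(half, half + n_windows)
    sl = slice(cfg.trim_head, n_windows - cfg.trim_tail)
    return WindowScores(transcript_id, centers[sl], means[sl], length)


def score_series(
    series: DilutionSeries, cfg: HuncConfig | None = None
) -> tuple[dict[str, WindowScores], dict[str, str]]:
    """Score every transcript of a series; returns (scores, skipped-with-reason)."""
    cfg = cfg or HuncConfig()
    scores: dict[str, WindowScores] = {}
    skipped: dict[str, str] = {}
    for tid in series.transcript_ids:
        try:
            scores[tid] = windowed_mad_scores(series, tid, cfg)
        except ValueError as exc:
            skipped[tid] = str(exc)
    return scores, skipped


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Index runs (start, stop) of consecutive True values."""
    runs = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return runs
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks, [idx.size - 1]))
    for a, b in zip(starts, stops):
        runs.append((int(idx[a]), int(idx[b]) + 1))
    return runs


def _candidate_intervals(
    ws: WindowScores, mask: np.ndarray, cfg: HuncConfig
) -> list[tuple[int, int]]:
    """Transcript-space spans of >= min_contiguous runs of flagged windows.

    A run spanning window centres [c_first, c_last] becomes the interval
    [c_first - w//2, c_last + w//2), clipped to transcript bounds.
    """
    half = cfg.window // 2
    out = []
    for a, b in _runs_above(mask):
        if b - a >= cfg.min_contiguous:
            start = max(int(ws.centers[a]) - half, 0)
            end = min(int(ws.centers[b - 1]) + half, ws.transcript_length)
            if start < end:
                out.append((start, end))
    return out


def _pooled_quantile(scores: Mapping[str, WindowScores], q: float) -> float:
    pooled = np.concatenate([ws.scores for ws in scores.values()])
    if pooled.size == 0:
        raise ValueError("no window scores to pool")
    # numpy's default linear interpolation == R's quantile type 7
    return float(np.quantile(pooled, q))


def _mean_score_in(ws: WindowScores | None, start: int, end: int) -> float:
    if ws is None:
        return np.nan
    sel = (ws.centers >= start) & (ws.centers < end)
    if not sel.any():
        return np.nan
    return float(ws.scores[sel].mean())


def _apply_mouse_filters(
    region: HuncRegion,
    mouse_fpkm: Sequence[Mapping[str, float]],
    mouse_coverage: Sequence[Mapping[str, np.ndarray]],
    cfg: HuncConfig,
) -> HuncRegion:
    """Mark a region failed if mouse background explains it; else pass it through.

    Drops the region when the transcript's mouse-only FPKM is >= the cap in
    either replicate, or when mean mouse-only depth exceeds the cap within
    the region or within ``flank`` bases on either side, in either replicate.
    """
    tid = region.transcript_id
    for rep_fpkm in mouse_fpkm:
        if rep_fpkm.get(tid, 0.0) >= cfg.mouse_fpkm_max:
            region.status = "failed:mouse_fpkm"
            return region
    for rep_cov in mouse_coverage:
        depths = rep_cov.get(tid)
        if depths is None:
            continue
        depths = np.asarray(depths, dtype=np.float64)
        length = len(depths)
        zones = (
            (region.start, region.end),
            (max(region.start - cfg.flank, 0), region.start),
            (region.end, min(region.end + cfg.flank, length)),
        )
        for a, b in zones:
            if a < b and depths[a:b].mean() > cfg.mouse_cov_max:
                region.status = "failed:mouse_coverage"
                return region
    return region


def call_hunc_regions(
    rep1_scores: Mapping[str, WindowScores],
    rep2_scores: Mapping[str, WindowScores],
    mouse_fpkm: Sequence[Mapping[str, float]],
    mouse_coverage: Sequence[Mapping[str, np.ndarray]],
    cfg: HuncConfig | None = None,
) -> HuncResult:
    """Call replicate-consistent hunc regions from two scored replicates.

    Per replicate the cutoff is the pooled ``mad_quantile`` quantile of all
    window scores; candidate intervals are runs of >= ``min_contiguous``
    strictly-above-cutoff windows. Candidates are intersected across
    replicates (>= 1 base overlap; the emitted interval is the
    intersection), then mouse-background filtered. Rejected candidates are
    returned with their failure provenance.
    """
    cfg = cfg or HuncConfig()
    cutoff1 = _pooled_quantile(rep1_scores, cfg.mad_quantile)
    cutoff2 = _pooled_quantile(rep2_scores, cfg.mad_quantile)

    regions: list[HuncRegion] = []
    rejected: list[HuncRegion] = []
    for tid in sorted(set(rep1_scores) & set(rep2_scores)):
        ws1, ws2 = rep1_scores[tid], rep2_scores[tid]
        cands1 = _candidate_intervals(ws1, ws1.scores > cutoff1, cfg)
        cands2 = _candidate_intervals(ws2, ws2.scores > cutoff2, cfg)
        for s1, e1 in cands1:
            for s2, e2 in cands2:
                start, end = max(s1, s2), min(e1, e2)
                if start >= end:  # abutting intervals do not count as overlap
                    continue
                mean_mad = float(
                    np.nanmean(
                        [_mean_score_in(ws1, start, end),
                         _mean_score_in(ws2, start, end)]
                    )
                )
                region = HuncRegion(tid, start, end, mean_mad)
                region = _apply_mouse_filters(region, mouse_fpkm, mouse_coverage, cfg)
                (regions if region.passed else rejected).append(region)
    return HuncResult(regions, rejected, (cutoff1, cutoff2))


def difference_regions(
    rep1_scores: Mapping[str, WindowScores],
    rep2_scores: Mapping[str, WindowScores],
    hunc: Sequence[HuncRegion],
    mouse_fpkm: Sequence[Mapping[str, float]],
    mouse_coverage: Sequence[Mapping[str, np.ndarray]],
    cfg: HuncConfig | None = None,
) -> HuncResult:
    """Regions where the two replicates' windowed MAD scores diverge.

    Per-window differences (replicate 1 minus replicate 2) are pooled over
    transcripts; the ``diff_quantiles`` percentiles give low/high cutoffs.
    Runs of >= ``min_contiguous`` windows below the low cutoff or above the
    high cutoff become candidates, which pass the same mouse filters and
    must lie farther than ``hunc_exclusion_distance`` bases from every
    already-called hunc region on the same transcript.
    """
    cfg = cfg or HuncConfig()
    shared = sorted(set(rep1_scores) & set(rep2_scores))
    diffs: dict[str, np.ndarray] = {}
    for tid in shared:
        ws1, ws2 = rep1_scores[tid], rep2_scores[tid]
        if len(ws1.scores) != len(ws2.scores):
            raise ValueError(f"{tid}: replicate score vectors are not aligned")
        diffs[tid] = ws1.scores - ws2.scores
    pooled = np.concatenate([diffs[tid] for tid in shared]) if shared else np.zeros(0)
    if pooled.size == 0:
        return HuncResult([], [], (np.nan, np.nan))
    low_cut = float(np.quantile(pooled, cfg.diff_quantiles[0]))
    high_cut = float(np.quantile(pooled, cfg.diff_quantiles[1]))

    hunc_by_tid: dict[str, list[HuncRegion]] = {}
    for region in hunc:
        hunc_by_tid.setdefault(region.transcript_id, []).append(region)

    regions: list[HuncRegion] = []
    rejected: list[HuncRegion] = []
    for tid in shared:
        ws = rep1_scores[tid]
        diff = diffs[tid]
        for direction, mask in ((1, diff > high_cut), (-1, diff < low_cut)):
            for start, end in _candidate_intervals(ws, mask, cfg):
                mean_mad = abs(_mean_score_in(
                    WindowScores(tid, ws.centers, diff, ws.transcript_length),
                    start, end,
                ))
                region = HuncRegion(
                    tid, start, end, mean_mad,
                    replicate_support=False, source="difference",
                    direction=direction,
                )
                near_hunc = any(
                    start - cfg.hunc_exclusion_distance <= h.end
                    and end + cfg.hunc_exclusion_distance >= h.start
                    for h in hunc_by_tid.get(tid, [])
                )
                if near_hunc:
                    region.status = "failed:near_hunc"
                else:
                    region = _apply_mouse_filters(
                        region, mouse_fpkm, mouse_coverage, cfg
                    )
                (regions if region.passed else rejected).append(region)
    return HuncResult(regions, rejected, (low_cut, high_cut))
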