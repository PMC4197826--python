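"""Independent brute-force oracles used by the equivalence tests.

Each oracle recomputes a statistic from first principles (enumeration,
plain loops, closed forms) without touching the implementation under test.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np


def sw_bruteforce(a: str, b: str, match: float, mismatch: float, gap: float) -> float:
    """Best local-alignment score by enumerating every substring pair and
    every global alignment between them (feasible for len <= ~6)."""

    @lru_cache(maxsize=None)
    def global_best(x: str, y: str) -> float:
        if not x and not y:
            return 0.0
        options = []
        if x and y:
            sub = match if x[0] == y[0] else mismatch
            options.append(sub + global_best(x[1:], y[1:]))
        if x:
            options.append(gap + global_best(x[1:], y))
        if y:
            options.append(gap + global_best(x, y[1:]))
        return max(options)

    best = 0.0
    for i in range(len(a) + 1):
        for j in range(i, len(a) + 1):
            for k in range(len(b) + 1):
                for l in range(k, len(b) + 1):
                    best = max(best, global_best(a[i:j], b[k:l]))
    return best


def mad_oracle(values) -> float:
    """MAD with constant 1 via explicit sorting-free definition."""
    values = list(values)
    med = float(np.median(values))
    return float(np.median([abs(v - med) for v in values]))


def windowed_mad_oracle(matrix: np.ndarray, window: int, trim_head: int,
                        trim_tail: int) -> tuple[list[int], list[float]]:
    """Plain-loop recomputation of normalization, per-base MAD, window means
    and trimming. Returns (centers, scores)."""
    n_cond, length = matrix.shape
    norm = np.zeros_like(matrix, dtype=float)
    for c in range(n_cond):
        row = matrix[c]
        lo, hi = row.min(), row.max()
        if hi > lo:
            norm[c] = (row - lo) / (hi - lo)
    mads = [mad_oracle(norm[:, i]) for i in range(length)]
    half = window // 2
    centers, scores = [], []
    for center in range(half, length - half):
        win = mads[center - half : center + half]
        centers.append(center)
        scores.append(sum(win) / window)
    n_windows = len(centers)
    sl = slice(trim_head, n_windows - trim_tail)
    return centers[sl], scores[sl]


def decile_fold_change_oracle(depths: np.ndarray, trim: int, min_length: int,
                              low_pct: float = 10.0, high_pct: float = 90.0):
    """Fold change by explicit sort-and-slice decile bins."""
    if len(depths) < min_length:
        return None
    inner = sorted(depths[trim : len(depths) - trim])
    n = len(inner)
    k_low = max(int(n * low_pct / 100), 1)
    k_high = max(int(n * (100 - high_pct) / 100), 1)
    bottom = sum(inner[:k_low]) / k_low
    top = sum(inner[-k_high:]) / k_high
    if bottom == 0:
        return math.inf
    return top / bottom


def ranksum_exact_oracle(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all group labelings.

    Requires a tie-free pooled sample. Returns (U for x, two-sided p).
    """
    x, y = list(x), list(y)
    n, m = len(x), len(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    rank = {v: i + 1 for i, v in enumerate(pooled)}

    def u_of(group):
        r = sum(rank[v] for v in group)
        return r - len(group) * (len(group) + 1) / 2

    u_obs = u_of(x)
    us = [
        u_of(combo)
        for combo in itertools.combinations(pooled, n)
    ]
    total = len(us)
    p_le = sum(u <= u_obs for u in us) / total
    p_ge = sum(u >= u_obs for u in us) / total
    return u_obs, min(1.0, 2 * min(p_le, p_ge))
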