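"""Per-transcript sequence characteristics.

Hexamer Shannon entropy (a sequence-complexity measure), GC fraction,
best local-alignment (Smith-Waterman) similarity to rRNA references, and
the no-selection vs rRNA-depleted coverage-drop score.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import Seq
from scipy.stats import entropy as shannon_entropy

from .models import TranscriptCoverage

__all__ = [
    "AlignScoring",
    "RRNA_SCORING",
    "hexamer_entropy",
    "gc_fraction",
    "smith_waterman_score",
    "rrna_similarity",
    "coverage_drop",
    "coverage_drop_table",
    "feature_table",
]

_ACGT = frozenset("ACGT")

#: Scoring used for similarity-to-rRNA screening. The permissive default
#: scheme (2/-1/-2) sits near the local-alignment phase transition, where
#: best scores between unrelated sequences grow linearly with length and no
#: longer discriminate homology; this stricter BLASTN-like scheme stays in
#: the logarithmic regime.
RRNA_SCORING = None  # assigned below once AlignScoring is defined


@dataclass(frozen=True)
class AlignScoring:
    """Local-alignment scoring scheme (linear gaps by default).

    ``gap`` is the per-base penalty; set ``gap_open`` for an affine scheme
    (then ``gap`` is the per-base extension penalty).
    """

    match: float = 2.0
    mismatch: float = -1.0
    gap: float = -2.0
    gap_open: float | None = None

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap > 0:
            raise ValueError("mismatch and gap penalties must be <= 0")

    def aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = self.match
        aligner.mismatch_score = self.mismatch
        aligner.open_gap_score = self.gap_open if self.gap_open is not None else self.gap
        aligner.extend_gap_score = self.gap
        return aligner


RRNA_SCORING = AlignScoring(match=2.0, mismatch=-3.0, gap=-5.0)


def hexamer_entropy(seq: str) -> float:
    """Shannon entropy (bits) of the overlapping-hexamer frequency distribution.

    All step-1 overlapping 6-mers are counted; hexamers containing a base
    outside {A,C,G,T} are skipped. Bounded by log2(4096) = 12 bits. Raises
    for sequences shorter than 6 bases; returns NaN when no valid hexamer
    exists.
    """
    seq = seq.upper()
    if len(seq) < 6:
        raise ValueError("sequence shorter than one hexamer")
    counts = Counter(
        seq[i : i + 6] for i in range(len(seq) - 5) if _ACGT.issuperset(seq[i : i + 6])
    )
    if not counts:
        return math.nan
    return float(shannon_entropy(np.array(list(counts.values()), float), base=2))


def gc_fraction(seq: str) -> float:
    """(G + C) / (A + C + G + T); other letters excluded from the denominator."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    counts = Counter(seq)
    denom = sum(counts[b] for b in "ACGT")
    if denom == 0:
        return math.nan
    return (counts["G"] + counts["C"]) / denom


def smith_waterman_score(
    a: str, b: str, scoring: AlignScoring | None = None
) -> float:
    """Best local-alignment score between two sequences (>= 0)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    scoring = scoring or AlignScoring()
    return float(scoring.aligner().score(a.upper(), b.upper()))


def rrna_similarity(
    seq: str,
    rrna_refs: Mapping[str, str] | Sequence[str],
    scoring: AlignScoring | None = None,
) -> float:
    """Best Smith-Waterman score of a transcript against rRNA references.

    Strand-agnostic: the maximum over all references of the forward sequence
    and its reverse complement.
    """
    refs = list(rrna_refs.values()) if isinstance(rrna_refs, Mapping) else list(rrna_refs)
    if not refs:
        raise ValueError("at least one rRNA reference is required")
    scoring = scoring or AlignScoring()
    rc = str(Seq(seq).reverse_complement())
    return max(
        smith_waterman_score(query, ref, scoring)
        for ref in refs
        for query in (seq, rc)
    )


def coverage_drop(
    no_sel: TranscriptCoverage,
    depleted: TranscriptCoverage,
    no_sel_scale: float = 1.0,
    depleted_scale: float = 1.0,
) -> float:
    """Relative coverage loss between the no-selection and depleted samples.

    ``max(0, 1 - mean(depleted)/mean(no_sel))`` on library-size-normalized
    depths (each sample divided by its scale; use
    :func:`coverage_drop_table` to derive the scales from pooled means). 1
    means complete loss, 0 no loss. NaN when the no-selection mean is zero.
    """
    if len(no_sel) != len(depleted):
        raise ValueError("coverage vectors must have equal length")
    mean_ns = no_sel.mean / no_sel_scale
    if mean_ns == 0:
        return math.nan
    mean_dep = depleted.mean / depleted_scale
    return max(0.0, 1.0 - mean_dep / mean_ns)


def coverage_drop_table(
    no_sel: Mapping[str, TranscriptCoverage],
    depleted: Mapping[str, TranscriptCoverage],
) -> pd.Series:
    """Per-transcript coverage drop with pooled-mean library normalization.

    Each sample is scaled so its pooled mean depth over all shared
    transcripts is 1, then the per-transcript drop is computed.
    """
    shared = sorted(set(no_sel) & set(depleted))
    if not shared:
        raise ValueError("no shared transcripts")
    scale_ns = float(np.concatenate([no_sel[t].depths for t in shared]).mean())
    scale_dep = float(np.concatenate([depleted[t].depths for t in shared]).mean())
    if scale_ns == 0 or scale_dep == 0:
        raise ValueError("a sample has zero pooled coverage")
    return pd.Series(
        {
            t: coverage_drop(no_sel[t], depleted[t], scale_ns, scale_dep)
            for t in shared
        },
        name="coverage_drop",
    )


def feature_table(
    seqs: Mapping[str, str],
    rrna_refs: Mapping[str, str],
    scoring: AlignScoring | None = None,
) -> pd.DataFrame:
    """Hexamer entropy, GC fraction and rRNA similarity for every transcript."""
    scoring = scoring or AlignScoring()
    rows = [
        {
            "transcript_id": tid,
            "hexamer_entropy": hexamer_entropy(seqs[tid]),
            "gc_fraction": gc_fraction(seqs[tid]),
            "rrna_score": rrna_similarity(seqs[tid], rrna_refs, scoring),
        }
        for tid in sorted(seqs)
    ]
    return pd.DataFrame(rows)
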