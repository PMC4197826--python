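"""Core in-memory containers for transcript-space coverage analysis.

All genomic intervals are 0-based, half-open (the bedGraph/BED convention).
Transcript space is 0-based and oriented 5'->3': position 0 is the leftmost
base of the first exon for a '+' transcript and the rightmost base of the
last exon for a '-' transcript.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ordered dilution-series condition labels, IVT-rich to IVT-free.
CONDITIONS = ("ivt_only", "1:1", "1:2", "1:10", "mouse_only")


class FormatError(ValueError):
    """A file violated its format contract (bad field, overlap, inconsistency)."""


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript's exon structure on the genome.

    Parameters
    ----------
    transcript_id : str
        Unique identifier.
    chrom : str
        Chromosome/contig name.
    strand : {'+', '-'}
        Transcription strand; decides which genomic end is the 5' end.
    exons : tuple of (int, int)
        Genomic exon intervals, 0-based half-open, sorted by start,
        non-overlapping, each non-empty.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"{self.transcript_id}: empty exon [{start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or are unsorted")
            prev_end = end

    @property
    def length(self) -> int:
        return sum(end - start for start, end in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic extent (first exon start, last exon end)."""
        return self.exons[0][0], self.exons[-1][1]

    def to_genomic(self, start: int, end: int) -> list[tuple[int, int]]:
        """Map a transcript-space interval [start, end) to genomic blocks.

        Returns one (gstart, gend) block per exon crossed, in genomic order.
        """
        if not (0 <= start < end <= self.length):
            raise ValueError(
                f"{self.transcript_id}: region [{start}, {end}) outside transcript "
                f"bounds [0, {self.length})"
            )
        exon_walk = self.exons if self.strand == "+" else tuple(reversed(self.exons))
        blocks: list[tuple[int, int]] = []
        offset = 0
        for gstart, gend in exon_walk:
            exon_len = gend - gstart
            lo = max(start - offset, 0)
            hi = min(end - offset, exon_len)
            if lo < hi:
                if self.strand == "+":
                    blocks.append((gstart + lo, gstart + hi))
                else:
                    blocks.append((gend - hi, gend - lo))
            offset += exon_len
        blocks.sort()
        return blocks


class GenomeCoverageTrack:
    """Sparse per-chromosome read-depth intervals; implicit depth 0 elsewhere.

    Intervals within a chromosome are non-overlapping and sorted. Depths are
    floats >= 0 (normalized tracks exist mid-pipeline).
    """

    def __init__(
        self,
        intervals: Mapping[str, Iterable[tuple[int, int, float]]] | None = None,
    ) -> None:
        # chrom -> (starts, ends, depths) as numpy arrays
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if intervals:
            for chrom, ivs in intervals.items():
                self.set_chrom(chrom, ivs)

    def set_chrom(self, chrom: str, ivs: Iterable[tuple[int, int, float]]) -> None:
        rows = sorted(ivs)
        starts = np.array([r[0] for r in rows], dtype=np.int64)
        ends = np.array([r[1] for r in rows], dtype=np.int64)
        depths = np.array([r[2] for r in rows], dtype=np.float64)
        if np.any(starts >= ends):
            raise FormatError(f"{chrom}: interval with start >= end")
        if np.any(depths < 0):
            raise FormatError(f"{chrom}: negative depth")
        if len(starts) > 1 and np.any(starts[1:] < ends[:-1]):
            raise FormatError(f"{chrom}: overlapping coverage intervals")
        self._data[chrom] = (starts, ends, depths)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def intervals(self, chrom: str) -> list[tuple[int, int, float]]:
        if chrom not in self._data:
            return []
        starts, ends, depths = self._data[chrom]
        return list(zip(starts.tolist(), ends.tolist(), depths.tolist()))

    def depth_array(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base depth over the genomic interval [start, end)."""
        out = np.zeros(end - start, dtype=np.float64)
        if chrom not in self._data or end <= start:
            return out
        starts, ends, depths = self._data[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            a = max(int(starts[i]), start)
            b = min(int(ends[i]), end)
            if a < b:
                out[a - start : b - start] = depths[i]
        return out


@dataclass
class TranscriptCoverage:
    """Per-base read depth in transcript space, oriented 5'->3'."""

    transcript_id: str
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=np.float64)
        if self.depths.ndim != 1:
            raise ValueError("depths must be a 1-D vector")
        if np.any(self.depths < 0):
            raise ValueError(f"{self.transcript_id}: negative depth")

    def __len__(self) -> int:
        return len(self.depths)

    @property
    def mean(self) -> float:
        return float(self.depths.mean()) if len(self.depths) else 0.0


def project_to_transcript(
    track: GenomeCoverageTrack, model: TranscriptModel
) -> TranscriptCoverage:
    """Project genome-space coverage into a transcript's 5'->3' coordinate frame.

    Intronic coverage is ignored. A chromosome absent from the track yields
    all-zero coverage with a logged warning (mouse-only samples legitimately
    lack coverage on most IVT transcripts).
    """
    if model.chrom not in track.chroms:
        logger.warning(
            "chromosome %s for %s not in coverage track; assuming zero coverage",
            model.chrom,
            model.transcript_id,
        )
    parts = [
        track.depth_array(model.chrom, start, end) for start, end in model.exons
    ]
    depths = np.concatenate(parts) if parts else np.zeros(0)
    if model.strand == "-":
        depths = depths[::-1]
    return TranscriptCoverage(model.transcript_id, depths)


def coverage_to_track(
    coverages: Mapping[str, TranscriptCoverage],
    models: Mapping[str, TranscriptModel],
) -> GenomeCoverageTrack:
    """Inverse projection: place transcript-space depths back onto the genome.

    Assumes transcripts are non-overlapping in genome space (the filtered IVT
    set satisfies this); overlapping models raise ``FormatError`` downstream.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for tid, cov in coverages.items():
        model = models[tid]
        if len(cov) != model.length:
            raise ValueError(f"{tid}: coverage length {len(cov)} != model length")
        depths = cov.depths if model.strand == "+" else cov.depths[::-1]
        offset = 0
        for gstart, gend in model.exons:
            n = gend - gstart
            seg = depths[offset : offset + n]
            offset += n
            # run-length encode the segment to keep the track sparse
            pos = 0
            while pos < n:
                run_end = pos + 1
                while run_end < n and seg[run_end] == seg[pos]:
                    run_end += 1
                if seg[pos] > 0:
                    per_chrom.setdefault(model.chrom, []).append(
                        (gstart + pos, gstart + run_end, float(seg[pos]))
                    )
                pos = run_end
    return GenomeCoverageTrack(per_chrom)


class FpkmTable:
    """Mapping (transcript_id, sample_label) -> FPKM, backed by a DataFrame."""

    COLUMNS = ("transcript_id", "sample", "fpkm")

    def __init__(self, df: pd.DataFrame | None = None) -> None:
        if df is None:
            df = pd.DataFrame(columns=list(self.COLUMNS))
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"FPKM table missing columns: {sorted(missing)}")
        if (df["fpkm"] < 0).any():
            raise FormatError("FPKM values must be >= 0")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_dict(cls, values: Mapping[tuple[str, str], float]) -> "FpkmTable":
        rows = [
            {"transcript_id": t, "sample": s, "fpkm": float(v)}
            for (t, s), v in values.items()
        ]
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    def get(self, transcript_id: str, sample: str, default: float = 0.0) -> float:
        sel = self.df[
            (self.df["transcript_id"] == transcript_id) & (self.df["sample"] == sample)
        ]
        if sel.empty:
            return default
        return float(sel["fpkm"].iloc[0])

    def sample_values(self, sample: str) -> pd.Series:
        sel = self.df[self.df["sample"] == sample]
        return sel.set_index("transcript_id")["fpkm"]

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample"].unique())

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "FpkmTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class DilutionSeries:
    """One replicate of the five-condition dilution series.

    ``coverage`` maps condition label -> transcript_id -> TranscriptCoverage;
    all five conditions must be present and per-transcript vectors must have
    equal length across conditions.
    """

    replicate: int
    coverage: dict[str, dict[str, TranscriptCoverage]]
    conditions: tuple[str, ...] = CONDITIONS

    def __post_init__(self) -> None:
        missing = set(self.conditions) - set(self.coverage)
        if missing:
            raise ValueError(f"dilution series missing conditions: {sorted(missing)}")
        for tid in self.transcript_ids:
            lengths = {
                len(self.coverage[c][tid]) for c in self.conditions
                if tid in self.coverage[c]
            }
            if len(lengths) > 1:
                raise ValueError(f"{tid}: coverage length differs across conditions")

    @property
    def transcript_ids(self) -> list[str]:
        ids: set[str] = set()
        for cond in self.conditions:
            ids.update(self.coverage[cond])
        return sorted(ids)

    def matrix(self, transcript_id: str) -> np.ndarray:
        """Condition x position depth matrix for one transcript (condition order)."""
        rows = []
        length = None
        for cond in self.conditions:
            cov = self.coverage[cond].get(transcript_id)
            if cov is not None:
                length = len(cov)
        if length is None:
            raise KeyError(transcript_id)
        for cond in self.conditions:
            cov = self.coverage[cond].get(transcript_id)
            rows.append(cov.depths if cov is not None else np.zeros(length))
        return np.vstack(rows)


def find_overlapping(models: Iterable[TranscriptModel]) -> set[str]:
    """Transcript ids sharing >= 1 genomic base with another model.

    Overlap is assessed on exon blocks, same chromosome, either strand.
    """
    events: dict[str, list[tuple[int, int, str]]] = {}
    for m in models:
        for start, end in m.exons:
            events.setdefault(m.chrom, []).append((start, end, m.transcript_id))
    flagged: set[str] = set()
    for chrom, ivs in events.items():
        ivs.sort()
        active: list[tuple[int, str]] = []  # (end, tid)
        for start, end, tid in ivs:
            active = [(e, t) for e, t in active if e > start]
            for _, other in active:
                if other != tid:
                    flagged.add(other)
                    flagged.add(tid)
            active.append((end, tid))
    return flagged


def filter_transcripts(
    models: Mapping[str, TranscriptModel],
    remove_ids: Iterable[str],
) -> dict[str, TranscriptModel]:
    """Drop transcripts on an explicit removal list (multi-locus/overlap flags)."""
    remove = set(remove_ids)
    unknown = remove - set(models)
    if unknown:
        logger.warning("removal list names %d unknown transcripts", len(unknown))
    return {tid: m for tid, m in models.items() if tid not in remove}
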