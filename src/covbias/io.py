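"""Readers and writers for the text formats the pipeline touches.

bedGraph (4-column coverage), BED12 gene models, BED6 region output, FASTA
sequences (via Biopython), and tab-delimited tables. All coordinates are
0-based half-open.
"""

from __future__ import annotations

import os
from typing import TYPE_CHECKING, Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import FormatError, GenomeCoverageTrack, TranscriptModel

if TYPE_CHECKING:  # pragma: no cover
    from .hunc import HuncRegion

__all__ = [
    "read_bedgraph",
    "write_bedgraph",
    "read_gene_models",
    "write_gene_models",
    "write_regions_bed",
    "read_fasta",
    "write_fasta",
]


def read_bedgraph(path: str | os.PathLike) -> GenomeCoverageTrack:
    """Parse a 4-column bedGraph file into a :class:`GenomeCoverageTrack`.

    track/browser/comment lines are skipped. Malformed lines (non-integer
    coordinates, start >= end, negative depth, wrong field count) raise
    :class:`FormatError` naming the line number, as do overlapping intervals
    within one chromosome.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 fields, got {len(fields)}"
                )
            chrom, s_start, s_end, s_depth = fields
            try:
                start, end = int(s_start), int(s_end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            try:
                depth = float(s_depth)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric depth") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            if depth < 0:
                raise FormatError(f"{path}:{lineno}: negative depth")
            per_chrom.setdefault(chrom, []).append((start, end, depth))
    return GenomeCoverageTrack(per_chrom)


def write_bedgraph(track: GenomeCoverageTrack, path: str | os.PathLike) -> None:
    """Write a coverage track as 4-column bedGraph (zero-depth intervals kept).

    Depths are written with shortest round-trip float formatting (integers
    bare), so write-then-read reproduces per-base depths exactly.
    """
    with open(path, "w") as fh:
        for chrom in track.chroms:
            for start, end, depth in track.intervals(chrom):
                text = str(int(depth)) if depth == int(depth) else repr(depth)
                fh.write(f"{chrom}\t{start}\t{end}\t{text}\n")


def _split_bed_list(raw: str, lineno: int, path) -> list[int]:
    items = [x for x in raw.rstrip(",").split(",") if x]
    try:
        return [int(x) for x in items]
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-integer block list") from exc


def read_gene_models(path: str | os.PathLike) -> dict[str, TranscriptModel]:
    """Parse BED12 gene models into TranscriptModels keyed by name."""
    out: dict[str, TranscriptModel] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 12:
                raise FormatError(f"{path}:{lineno}: BED12 needs 12 fields")
            chrom = fields[0]
            try:
                chrom_start, chrom_end = int(fields[1]), int(fields[2])
                block_count = int(fields[9])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            name, strand = fields[3], fields[5]
            sizes = _split_bed_list(fields[10], lineno, path)
            starts = _split_bed_list(fields[11], lineno, path)
            if len(sizes) != block_count or len(starts) != block_count:
                raise FormatError(
                    f"{path}:{lineno}: blockCount={block_count} but "
                    f"{len(sizes)} sizes / {len(starts)} starts listed"
                )
            exons = tuple(
                (chrom_start + st, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            )
            if any(end > chrom_end for _, end in exons):
                raise FormatError(f"{path}:{lineno}: block extends past chromEnd")
            if name in out:
                raise FormatError(f"{path}:{lineno}: duplicate transcript {name}")
            try:
                out[name] = TranscriptModel(name, chrom, strand, exons)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_gene_models(
    models: Mapping[str, TranscriptModel], path: str | os.PathLike
) -> None:
    """Write TranscriptModels as BED12 (one line per transcript)."""
    with open(path, "w") as fh:
        for tid in sorted(models):
            m = models[tid]
            span_start, span_end = m.span
            sizes = ",".join(str(e - s) for s, e in m.exons)
            starts = ",".join(str(s - span_start) for s, _ in m.exons)
            fh.write(
                f"{m.chrom}\t{span_start}\t{span_end}\t{tid}\t0\t{m.strand}\t"
                f"{span_start}\t{span_end}\t0\t{len(m.exons)}\t{sizes}\t{starts}\n"
            )


def write_regions_bed(
    regions: Iterable["HuncRegion"],
    models: Mapping[str, TranscriptModel],
    path: str | os.PathLike,
) -> None:
    """Write called regions as BED6 in genomic coordinates.

    Transcript-space intervals are inverse-projected through the exon
    structure; a region spanning an exon junction emits one line per genomic
    block. The score column carries the region's mean windowed MAD scaled to
    [0, 1000].
    """
    with open(path, "w") as fh:
        fh.write("# covbias regions: chrom start end transcript_id score strand\n")
        for region in regions:
            model = models.get(region.transcript_id)
            if model is None:
                raise KeyError(f"no model for {region.transcript_id}")
            score = int(round(min(max(region.mean_mad, 0.0), 1.0) * 1000))
            for gstart, gend in model.to_genomic(region.start, region.end):
                fh.write(
                    f"{model.chrom}\t{gstart}\t{gend}\t{region.transcript_id}\t"
                    f"{score}\t{model.strand}\n"
                )


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seqs[name]), id=name, description="") for name in sorted(seqs)
    ]
    SeqIO.write(records, str(path), "fasta")
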