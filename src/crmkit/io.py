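"""Shared file I/O for genomic text formats.

All genomic intervals handled by this package are 0-based half-open.
UCSC-style region strings (``chr2:113,326,224-113,894,862``) are 1-based
inclusive and are converted on parsing. FASTA is written at a fixed line
width of 60 so that ``write(read(f))`` is byte-identical for canonical
input.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import AlignIO, SeqIO, motifs as bio_motifs
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FASTA_LINE_WIDTH = 60

__all__ = [
    "IntervalRecord",
    "MalformedRecordError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_bed",
    "write_bed",
    "write_bedgraph",
    "read_jaspar",
    "read_aligned_fasta",
    "write_aligned_fasta",
    "parse_region",
    "format_region",
]


class MalformedRecordError(ValueError):
    """Raised for malformed file records; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class IntervalRecord:
    """One BED-style genomic interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered mapping of id -> uppercase sequence."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise MalformedRecordError(f"duplicate FASTA id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise MalformedRecordError(f"no FASTA records found in {path}")
    return records


def write_fasta(path: str | Path, sequences: dict[str, str] | Iterable[tuple[str, str]]) -> None:
    items = sequences.items() if isinstance(sequences, dict) else sequences
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), FASTA_LINE_WIDTH):
                fh.write(seq[i : i + FASTA_LINE_WIDTH] + "\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTQ records as (id, sequence); qualities are discarded."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]], quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[IntervalRecord]:
    intervals: list[IntervalRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise MalformedRecordError("BED record has fewer than 3 fields", lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise MalformedRecordError(f"non-integer BED coordinate: {exc}", lineno)
            name = fields[3] if len(fields) > 3 else "."
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError as exc:
                raise MalformedRecordError(f"non-numeric BED score: {exc}", lineno)
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(IntervalRecord(fields[0], start, end, name, score, strand))
            except ValueError as exc:
                raise MalformedRecordError(str(exc), lineno)
    return intervals


def _fmt_score(score: float) -> str:
    if float(score).is_integer():
        return str(int(score))
    return format(score, "g")


def write_bed(path: str | Path, intervals: Iterable[IntervalRecord]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{_fmt_score(iv.score)}\t{iv.strand}\n"
            )


def write_bedgraph(
    path: str | Path,
    records: Iterable[tuple[str, int, int, float]],
    track_name: str | None = None,
) -> None:
    """Write 4-column bedGraph records (chrom, start, end, value)."""
    with open(path, "w") as fh:
        if track_name:
            fh.write(f'track type=bedGraph name="{track_name}"\n')
        for chrom, start, end, value in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


# ---------------------------------------------------------------------------
# JASPAR matrices and alignments
# ---------------------------------------------------------------------------

def read_jaspar(path: str | Path) -> list[tuple[str, np.ndarray]]:
    """Read JASPAR-format count matrices.

    Returns a list of (matrix id, counts) with counts shaped (4, L) in
    A, C, G, T row order.
    """
    out: list[tuple[str, np.ndarray]] = []
    with open(path) as fh:
        for motif in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([motif.counts[b] for b in "ACGT"], dtype=float)
            ident = motif.matrix_id or motif.name
            out.append((ident, counts))
    if not out:
        raise MalformedRecordError(f"no JASPAR matrices found in {path}")
    return out


def read_aligned_fasta(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA (equal-length rows, '-' gaps)."""
    aln = AlignIO.read(str(path), "fasta")
    return {rec.id: str(rec.seq).upper() for rec in aln}


def write_aligned_fasta(path: str | Path, alignment: dict[str, str]) -> None:
    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in alignment.items()]
    )
    with open(path, "w") as fh:
        AlignIO.write(msa, fh, "fasta")


# ---------------------------------------------------------------------------
# Region strings
# ---------------------------------------------------------------------------

def parse_region(region: str) -> tuple[str, int, int]:
    """Parse a UCSC-style region string into (chrom, start, end).

    The input is 1-based inclusive (``chr2:113326224-113894862``); the
    result is 0-based half-open. Commas and the typographic en dash are
    accepted.
    """
    cleaned = region.replace(",", "").replace("–", "-")
    if ":" not in cleaned:
        raise ValueError(f"malformed region string {region!r} (expected chrom:start-end)")
    chrom, _, span = cleaned.partition(":")
    lo, sep, hi = span.partition("-")
    if not sep or not chrom:
        raise ValueError(f"malformed region string {region!r} (expected chrom:start-end)")
    try:
        start1, end1 = int(lo), int(hi)
    except ValueError:
        raise ValueError(f"non-integer coordinates in region string {region!r}")
    if start1 < 1 or end1 < start1:
        raise ValueError(f"empty or inverted region {region!r}")
    return chrom, start1 - 1, end1


def format_region(chrom: str, start: int, end: int) -> str:
    """Inverse of :func:`parse_region` (0-based half-open in, 1-based out)."""
    return f"{chrom}:{start + 1}-{end}"
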