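"""Sequence containers, on-disk formats and shared nucleotide utilities.

All genomic coordinates are 0-based half-open (BED convention) everywhere in
the package; 1-based coordinates appear only in human-readable reports.
FASTQ qualities are parsed but never used downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "SeqRecord",
    "GenomicInterval",
    "DegenerateMotif",
    "IUPAC_CODES",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_bed",
    "write_bed",
    "reverse_complement",
    "translate",
    "degenerate_match",
]

_NUC_ALPHABET = set("ACGTN")
_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY*X-")

#: IUPAC nucleotide ambiguity codes and the concrete bases each matches.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence (nucleotide or one-letter amino acid), upper case."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)

    def validate_alphabet(self, kind: str = "nucleotide") -> "SeqRecord":
        allowed = _NUC_ALPHABET if kind == "nucleotide" else _AA_ALPHABET
        bad = set(self.sequence) - allowed
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid {kind} characters {sorted(bad)}"
            )
        return self


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open [start, end) interval on a named chromosome."""

    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chromosome}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class DegenerateMotif:
    """An IUPAC degenerate nucleotide pattern (e.g. an enrichment probe)."""

    pattern: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", self.pattern.upper())
        bad = set(self.pattern) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"invalid IUPAC code(s) {sorted(bad)} in motif")

    def __len__(self) -> int:
        return len(self.pattern)

    def expansions(self) -> list[str]:
        """All concrete strings the motif matches (use only for small motifs)."""
        out = [""]
        for code in self.pattern:
            out = [p + b for p in out for b in sorted(IUPAC_CODES[code])]
        return out


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file; sequences are upper-cased, duplicate ids rejected."""
    records = []
    seen: set[str] = set()
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
            seen.add(rec.id)
            desc = rec.description[len(rec.id):].strip()
            records.append(SeqRecord(rec.id, str(rec.seq), desc))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def format_fasta(records: Sequence[SeqRecord], width: int = 60) -> str:
    buf = io.StringIO()
    for rec in records:
        header = rec.id if not rec.description else f"{rec.id} {rec.description}"
        buf.write(f">{header}\n")
        for i in range(0, len(rec.sequence), width):
            buf.write(rec.sequence[i : i + width])
            buf.write("\n")
    return buf.getvalue()


def write_fasta(records: Sequence[SeqRecord], path: str | Path, width: int = 60) -> None:
    Path(path).write_text(format_fasta(records, width=width))


def read_fastq(path: str | Path) -> list[SeqRecord]:
    """Read FASTQ; qualities are discarded (the pipeline never uses them)."""
    records = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            desc = rec.description[len(rec.id):].strip()
            records.append(SeqRecord(rec.id, str(rec.seq), desc))
    return records


def format_fastq(records: Sequence[SeqRecord], quality_char: str = "?") -> str:
    buf = io.StringIO()
    for rec in records:
        header = rec.id if not rec.description else f"{rec.id} {rec.description}"
        buf.write(f"@{header}\n{rec.sequence}\n+\n{quality_char * len(rec.sequence)}\n")
    return buf.getvalue()


def write_fastq(records: Sequence[SeqRecord], path: str | Path, quality_char: str = "?") -> None:
    Path(path).write_text(format_fastq(records, quality_char=quality_char))


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a 3+ column BED file (0-based half-open), strand from column 6."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ValueError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            strand = fields[5] if len(fields) >= 6 else "+"
            intervals.append(GenomicInterval(chrom, start, end, strand))
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path,
              names: Sequence[str] | None = None) -> None:
    """Write 3-column BED (or 6-column when names are given)."""
    lines = []
    for i, iv in enumerate(intervals):
        if names is None:
            lines.append(f"{iv.chromosome}\t{iv.start}\t{iv.end}")
        else:
            lines.append(
                f"{iv.chromosome}\t{iv.start}\t{iv.end}\t{names[i]}\t0\t{iv.strand}"
            )
    Path(path).write_text("".join(line + "\n" for line in lines))


# ---------------------------------------------------------------------------
# Sequence utilities
# ---------------------------------------------------------------------------


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(cds: str) -> str:
    """Translate a nucleotide string with the standard code ('*' for stops).

    Translates floor(len/3) codons in frame 0; no frame guessing.
    """
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    usable = len(cds) - len(cds) % 3
    return str(Seq(cds[:usable]).translate())


def degenerate_match(motif: DegenerateMotif | str, seq: str) -> list[int]:
    """All 0-based positions where the IUPAC motif matches (overlaps included)."""
    if isinstance(motif, str):
        motif = DegenerateMotif(motif)
    pattern = motif.pattern
    seq = seq.upper()
    m, n = len(pattern), len(seq)
    sets = [IUPAC_CODES[c] for c in pattern]
    hits = []
    for p in range(n - m + 1):
        if all(seq[p + i] in sets[i] for i in range(m)):
            hits.append(p)
    return hits
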