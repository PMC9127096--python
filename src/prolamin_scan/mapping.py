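"""Minimal long-read mapper: canonical k-mer anchors + collinear chaining.

High-identity long reads need only sparse anchoring, so the mapper finds
exact canonical k-mer matches, thins them to roughly one anchor per
``anchor_stride`` read bases, chains the best collinear subset per
(chromosome, strand) with an exact dynamic program, and estimates identity
from anchor coverage.  No base-level alignment or CIGAR is produced; the
consensus stage re-anchors reads per locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .io_core import GenomicInterval, SeqRecord, reverse_complement

__all__ = [
    "KmerIndex", "Anchor", "AlignmentRecord", "index_reference", "map_read",
    "chain_anchors", "write_alignments", "read_alignments",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def _canonical(kmer: str) -> tuple[str, bool]:
    """Canonical form and whether the forward orientation is canonical."""
    rc = kmer.translate(_COMP)[::-1]
    return (kmer, True) if kmer <= rc else (rc, False)


@dataclass
class KmerIndex:
    k: int
    max_occ: int
    # canonical k-mer -> list of (chromosome, position, forward_is_canonical)
    positions: dict[str, list[tuple[str, int, bool]]]
    chrom_lengths: dict[str, int]


def index_reference(genome: Sequence[SeqRecord], k: int = 15,
                    max_occ: int = 50) -> KmerIndex:
    """Index every canonical k-mer; drop k-mers above the repeat ceiling."""
    if k % 2 == 0 or not 11 <= k <= 21:
        raise ValueError("k must be odd in [11, 21]")
    if not genome or any(len(rec) == 0 for rec in genome):
        raise ValueError("reference sequences must be non-empty")
    positions: dict[str, list[tuple[str, int, bool]]] = {}
    lengths: dict[str, int] = {}
    for rec in genome:
        seq = rec.sequence
        lengths[rec.id] = len(seq)
        for pos in range(len(seq) - k + 1):
            kmer = seq[pos:pos + k]
            if "N" in kmer:
                continue
            canon, fwd = _canonical(kmer)
            positions.setdefault(canon, []).append((rec.id, pos, fwd))
    for key in [key for key, hits in positions.items() if len(hits) > max_occ]:
        del positions[key]
    return KmerIndex(k, max_occ, positions, lengths)


@dataclass(frozen=True)
class Anchor:
    """Exact k-mer match: read offset (strand-normalised) vs target offset."""

    read_pos: int
    target_pos: int


def chain_anchors(anchors: Sequence[Anchor], max_gap: int = 500
                  ) -> list[Anchor]:
    """Largest collinear anchor subset (exact O(n^2) dynamic program).

    Collinear: strictly increasing in both read and target coordinates with
    successive gaps at most ``max_gap`` on both axes.  Ties are broken toward
    the earliest (target_pos, read_pos) chain for determinism.
    """
    if not anchors:
        return []
    order = sorted(range(len(anchors)),
                   key=lambda i: (anchors[i].target_pos, anchors[i].read_pos))
    arr = [anchors[i] for i in order]
    n = len(arr)
    best = [1] * n
    prev = [-1] * n
    for j in range(n):
        aj = arr[j]
        for i in range(j):
            ai = arr[i]
            if (ai.read_pos < aj.read_pos and ai.target_pos < aj.target_pos
                    and aj.read_pos - ai.read_pos <= max_gap
                    and aj.target_pos - ai.target_pos <= max_gap
                    and best[i] + 1 > best[j]):
                best[j] = best[i] + 1
                prev[j] = i
    end = max(range(n), key=lambda j: (best[j], -arr[j].target_pos, -arr[j].read_pos))
    chain = []
    while end != -1:
        chain.append(arr[end])
        end = prev[end]
    return chain[::-1]


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    target: GenomicInterval | None
    read_span: tuple[int, int]
    n_anchors: int
    identity_estimate: float
    mapped: bool

    def to_tsv_row(self) -> str:
        if self.target is None or not self.mapped:
            return f"{self.read_id}\t*\t0\t0\t+\t0\t0\t0\t0.0"
        t = self.target
        return (f"{self.read_id}\t{t.chromosome}\t{t.start}\t{t.end}\t{t.strand}"
                f"\t{self.read_span[0]}\t{self.read_span[1]}"
                f"\t{self.n_anchors}\t{self.identity_estimate:.4f}")


_BAND_TOL = 30          # max offset drift within one diagonal band
_EXACT_DP_LIMIT = 80    # anchor count up to which the exact DP is used


def _chain_banded(anchors: list[Anchor], max_gap: int, k: int) -> list[Anchor]:
    """Scalable chaining: cluster anchors into diagonal bands, then run a
    small DP over bands (monotone in read and target, gaps <= max_gap).

    Bands absorb small indel drift (<= _BAND_TOL); separate bands arise from
    introns or from hits to distinct gene copies, and the DP keeps only a
    collinear, non-overlapping subset of them.
    """
    anchors = sorted(anchors, key=lambda a: (a.target_pos - a.read_pos,
                                             a.read_pos))
    bands: list[list[Anchor]] = []
    for a in anchors:
        off = a.target_pos - a.read_pos
        if bands and off - (bands[-1][-1].target_pos - bands[-1][-1].read_pos) <= _BAND_TOL:
            bands[-1].append(a)
        else:
            bands.append([a])
    # summarise each band; deduplicate anchors sharing a read position
    summaries = []
    for band in bands:
        band.sort(key=lambda a: (a.read_pos, a.target_pos))
        dedup = []
        last_q = -1
        for a in band:
            if a.read_pos != last_q:
                dedup.append(a)
                last_q = a.read_pos
        summaries.append((dedup[0].read_pos, dedup[-1].read_pos + k,
                          dedup[0].target_pos, dedup[-1].target_pos + k, dedup))
    summaries.sort(key=lambda s: (s[0], s[2]))
    n = len(summaries)
    score = [len(s[4]) for s in summaries]
    best = list(score)
    prev = [-1] * n
    for j in range(n):
        qj, _, tj, _, _ = summaries[j]
        for i in range(j):
            _, qi_end, _, ti_end, _ = summaries[i]
            if (qj >= qi_end - k and tj >= ti_end - k
                    and qj - qi_end <= max_gap and tj - ti_end <= max_gap
                    and best[i] + score[j] > best[j]):
                best[j] = best[i] + score[j]
                prev[j] = i
    end = max(range(n), key=lambda j: (best[j], -summaries[j][2]))
    chosen: list[Anchor] = []
    while end != -1:
        chosen = summaries[end][4] + chosen
        end = prev[end]
    return chosen


def map_read(read: SeqRecord, index: KmerIndex, max_gap: int = 500,
             min_anchors: int = 3, min_span: int = 100) -> AlignmentRecord:
    """Map one read; unmapped is a value (mapped=False), never an error."""
    k = index.k
    seq = read.sequence
    n = len(seq)
    groups: dict[tuple[str, str], list[Anchor]] = {}
    for i in range(n - k + 1):
        kmer = seq[i:i + k]
        if "N" in kmer:
            continue
        canon, read_fwd = _canonical(kmer)
        hits = index.positions.get(canon)
        if not hits:
            continue
        for chrom, tpos, ref_fwd in hits:
            strand = "+" if ref_fwd == read_fwd else "-"
            qpos = i if strand == "+" else n - k - i
            groups.setdefault((chrom, strand), []).append(Anchor(qpos, tpos))

    best_chain: list[Anchor] = []
    best_key: tuple = ()
    for (chrom, strand), anchors in groups.items():
        if len(anchors) <= _EXACT_DP_LIMIT:
            chain = chain_anchors(anchors, max_gap)
        else:
            chain = _chain_banded(anchors, max_gap, k)
        key = (-len(chain), chrom, chain[0].target_pos if chain else 0, strand)
        if not best_chain or key < best_key:
            best_chain, best_key = chain, key

    if not best_chain:
        return AlignmentRecord(read.id, None, (0, 0), 0, 0.0, False)

    chrom, strand = best_key[1], best_key[3]
    chain = best_chain
    qmin, qmax = chain[0].read_pos, chain[-1].read_pos + k
    tmin, tmax = chain[0].target_pos, chain[-1].target_pos + k
    # extend the target interval to the read ends, clipped to the chromosome
    clen = index.chrom_lengths[chrom]
    tstart = max(0, tmin - qmin)
    tend = min(clen, tmax + (n - qmax))
    span = tmax - tmin
    covered = 0
    last_end = -1
    for a in chain:
        s, e = max(a.read_pos, last_end), a.read_pos + k
        if e > s:
            covered += e - s
            last_end = e
    identity = covered / (qmax - qmin) if qmax > qmin else 0.0
    mapped = len(chain) >= min_anchors and span >= min_span
    if strand == "+":
        read_span = (qmin, qmax)
    else:
        read_span = (n - qmax, n - qmin)
    target = GenomicInterval(chrom, tstart, tend, strand)
    return AlignmentRecord(read.id, target, read_span, len(chain),
                           min(identity, 1.0), mapped)


ALN_HEADER = "read_id\tchrom\tstart\tend\tstrand\tread_start\tread_end\tn_anchors\tidentity"


def write_alignments(alignments: Iterable[AlignmentRecord],
                     path: str | Path) -> None:
    lines = [ALN_HEADER]
    lines += [a.to_tsv_row() for a in alignments]
    Path(path).write_text("\n".join(lines) + "\n")


def read_alignments(path: str | Path) -> list[AlignmentRecord]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != ALN_HEADER:
            raise ValueError(f"unexpected alignment header in {path}")
        for line in fh:
            (read_id, chrom, start, end, strand, rs, re_, na, ident
             ) = line.rstrip("\n").split("\t")
            if chrom == "*":
                out.append(AlignmentRecord(read_id, None, (0, 0), 0, 0.0, False))
            else:
                out.append(AlignmentRecord(
                    read_id, GenomicInterval(chrom, int(start), int(end), strand),
                    (int(rs), int(re_)), int(na), float(ident), True))
    return out
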