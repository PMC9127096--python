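"""Locus merging, reduced-reference extraction and pileup consensus.

Mapped read intervals are merged (overlapping or book-ended) into target
loci, the genome is reduced to those loci (plus flanks), and per-locus
consensus sequences are called from a substitution-only pileup: reads are
re-anchored to the locus reference by unique k-mer matches, every read base
is placed at the offset of its nearest anchor, and each column takes the
majority base (ties and low-depth columns fall back to the reference).
Insertions in reads are skipped by the placement step and read deletions
simply count as absent coverage.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_core import GenomicInterval, SeqRecord
from .mapping import AlignmentRecord

__all__ = [
    "Locus", "ConsensusSequence", "merge_loci", "extract_reduced_reference",
    "anchor_read_to_reference", "call_consensus",
]


@dataclass(frozen=True)
class Locus:
    locus_id: str
    interval: GenomicInterval
    n_supporting_reads: int


@dataclass
class ConsensusSequence:
    locus_id: str
    sequence: str
    depth: list[int]
    variants: list[tuple[int, str, str, float]]   # (pos, ref, alt, fraction)
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if len(self.depth) != len(self.sequence):
            raise ValueError("depth track must match sequence length")

    @classmethod
    def from_sequence(cls, locus_id: str, sequence: str,
                      depth: int = 1) -> "ConsensusSequence":
        """Wrap a bare sequence (uniform coverage) for downstream analysis."""
        return cls(locus_id, sequence.upper(), [depth] * len(sequence), [])


def merge_loci(alignments: Sequence[AlignmentRecord],
               min_reads: int = 3) -> list[Locus]:
    """Merge mapped intervals (overlap >= 1 bp or book-ended) into loci.

    Output is sorted by (chromosome, start); loci supported by fewer than
    ``min_reads`` reads are dropped.  Idempotent: merging the merged
    intervals again changes nothing.
    """
    ivs = sorted((a.target for a in alignments if a.mapped and a.target),
                 key=lambda t: (t.chromosome, t.start, t.end))
    merged: list[Locus] = []
    cur: list | None = None   # [chrom, start, end, count]
    for iv in ivs:
        if cur is not None and iv.chromosome == cur[0] and iv.start <= cur[2]:
            cur[2] = max(cur[2], iv.end)
            cur[3] += 1
        else:
            if cur is not None:
                merged.append(cur)
            cur = [iv.chromosome, iv.start, iv.end, 1]
    if cur is not None:
        merged.append(cur)
    return [Locus(f"{c}-{s}", GenomicInterval(c, s, e, "+"), n)
            for c, s, e, n in merged if n >= min_reads]


def extract_reduced_reference(genome: Sequence[SeqRecord],
                              loci: Sequence[Locus],
                              flank: int = 50) -> list[SeqRecord]:
    """One record per locus, id "chrom-start", flanks clipped at chromosome ends."""
    by_name = {rec.id: rec.sequence for rec in genome}
    out = []
    for locus in loci:
        iv = locus.interval
        try:
            seq = by_name[iv.chromosome]
        except KeyError:
            raise ValueError(f"locus on unknown chromosome {iv.chromosome}")
        if iv.end > len(seq):
            raise ValueError(
                f"locus {locus.locus_id} extends past the end of {iv.chromosome}")
        s = max(0, iv.start - flank)
        e = min(len(seq), iv.end + flank)
        out.append(SeqRecord(locus.locus_id, seq[s:e],
                             description=f"{iv.chromosome}:{s}-{e}"))
    return out


def _lis_filter(anchors: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest strictly-increasing (in target) subsequence, anchors sorted by
    read position; removes spurious off-diagonal matches."""
    tails: list[int] = []        # target positions
    tails_idx: list[int] = []
    prev = [-1] * len(anchors)
    for i, (_, t) in enumerate(anchors):
        j = bisect.bisect_left(tails, t)
        if j == len(tails):
            tails.append(t)
            tails_idx.append(i)
        else:
            tails[j] = t
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    out = []
    i = tails_idx[-1] if tails_idx else -1
    while i != -1:
        out.append(anchors[i])
        i = prev[i]
    return out[::-1]


def anchor_read_to_reference(read_seq: str, ref_seq: str, k: int = 15
                             ) -> list[tuple[int, str]]:
    """Place read bases on the locus reference via unique k-mer anchors.

    Anchors are k-mers unique in both read and reference; after a
    longest-increasing-subsequence filter, each read base takes the offset
    of its nearest anchor (so exon blocks separated by introns land at their
    own offsets).  Returns (reference position, base) pairs.
    """
    ref_pos: dict[str, int] = {}
    ref_dup: set[str] = set()
    for p in range(len(ref_seq) - k + 1):
        km = ref_seq[p:p + k]
        if km in ref_pos or km in ref_dup:
            ref_dup.add(km)
            ref_pos.pop(km, None)
        else:
            ref_pos[km] = p
    read_seen: dict[str, int] = {}
    read_dup: set[str] = set()
    for p in range(len(read_seq) - k + 1):
        km = read_seq[p:p + k]
        if km in read_seen or km in read_dup:
            read_dup.add(km)
            read_seen.pop(km, None)
        else:
            read_seen[km] = p
    anchors = sorted((rp, ref_pos[km]) for km, rp in read_seen.items()
                     if km in ref_pos)
    if not anchors:
        return []
    anchors = _lis_filter(anchors)
    # merge consecutive same-offset anchors into runs; a run spans an exon
    # (or indel-free block) even across gaps left by substitution errors
    runs: list[list[int]] = []   # [q_start, q_end, offset]
    for rp, tp in anchors:
        off = tp - rp
        if runs and runs[-1][2] == off:
            runs[-1][1] = rp + k
        else:
            runs.append([rp, rp + k, off])
    # bases outside every run are either non-reference termini (adapter,
    # poly-A) or sit between blocks of conflicting offset (e.g. next to an
    # intron junction disrupted by an error): both are dropped, not guessed
    placements = []
    ref_len = len(ref_seq)
    for q_start, q_end, off in runs:
        for i in range(q_start, q_end):
            tpos = off + i
            if 0 <= tpos < ref_len:
                placements.append((tpos, read_seq[i]))
    return placements


_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_IDX_BASE = "ACGT"


def call_consensus(placements: Sequence[Sequence[tuple[int, str]]],
                   locus_ref: SeqRecord,
                   min_depth: int = 3,
                   min_alt_fraction: float = 0.2) -> ConsensusSequence:
    """Majority-rule pileup consensus against the locus reference.

    Per column: below ``min_depth`` the reference base is emitted; otherwise
    the majority base (ties resolve to the reference, then alphabetically).
    A variant row is recorded when the majority differs from the reference
    or another allele reaches ``min_alt_fraction``.  With no reads at all
    the consensus is the reference, flagged low-confidence.
    """
    ref = locus_ref.sequence
    L = len(ref)
    counts = np.zeros((4, L), dtype=np.int32)
    for read_placements in placements:
        for tpos, base in read_placements:
            bi = _BASE_IDX.get(base)
            if bi is not None and 0 <= tpos < L:
                counts[bi, tpos] += 1
    depth = counts.sum(axis=0)
    out = list(ref)
    variants: list[tuple[int, str, str, float]] = []
    for pos in np.nonzero(depth >= min_depth)[0]:
        col = counts[:, pos]
        d = int(depth[pos])
        top = int(col.max())
        winners = [_IDX_BASE[i] for i in range(4) if col[i] == top]
        ref_base = ref[pos]
        call = ref_base if ref_base in winners else winners[0]
        out[pos] = call
        if call != ref_base:
            variants.append((int(pos), ref_base, call, top / d))
        for i in range(4):
            alt = _IDX_BASE[i]
            if alt in (call, ref_base):
                continue
            frac = col[i] / d
            if frac >= min_alt_fraction:
                variants.append((int(pos), ref_base, alt, float(frac)))
    low_conf = not any(len(p) for p in placements)
    return ConsensusSequence(locus_ref.id, "".join(out), depth.tolist(),
                             sorted(variants), low_conf)
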