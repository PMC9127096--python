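"""Jukes-Cantor distances, neighbor-joining trees and family assignment.

The substitution model is Jukes-Cantor: with p the proportion of differing
sites over comparable columns, d = -(3/4) ln(1 - 4p/3) substitutions/site.
Trees are built by standard neighbor-joining (exact on additive matrices),
and genes are assigned to families by the nearest exemplar after global
pairwise alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align

from .io_core import SeqRecord

__all__ = [
    "JCSaturationError", "DistanceMatrix", "FamilyAssignment",
    "jc_distance", "pairwise_align", "nj_tree", "assign_family",
    "distance_matrix_from_sequences",
]


class JCSaturationError(ValueError):
    """Raised when p >= 0.75, outside the Jukes-Cantor domain."""


def jc_distance(a: str, b: str) -> float:
    """Jukes-Cantor distance between two aligned nucleotide strings.

    Columns where either sequence has a gap or N are excluded; at least one
    comparable column is required.
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    comparable = 0
    mismatches = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "ACGT" and y in "ACGT":
            comparable += 1
            if x != y:
                mismatches += 1
    if comparable == 0:
        raise ValueError("no comparable columns")
    p = mismatches / comparable
    if p >= 0.75:
        raise JCSaturationError(
            f"proportion of differing sites p={p:.3f} >= 0.75: "
            "Jukes-Cantor distance is undefined (saturated)")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) if p else 0.0


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -2
_aligner.extend_gap_score = -2


def pairwise_align(a: str, b: str) -> tuple[str, str]:
    """Global alignment (match +1, mismatch -1, linear gap -2).

    Deterministic: the aligner's canonical first optimal alignment is used.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aln = _aligner.align(a.upper(), b.upper())[0]
    return str(aln[0]), str(aln[1])


def alignment_score(a: str, b: str) -> float:
    return _aligner.score(a.upper(), b.upper())


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.isfinite(self.d).all():
            raise ValueError("distances must be finite")


def distance_matrix_from_sequences(records: Sequence[SeqRecord]
                                   ) -> DistanceMatrix:
    """All-pairs JC distances after pairwise global alignment."""
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ai, aj = pairwise_align(records[i].sequence, records[j].sequence)
            try:
                dist = jc_distance(ai, aj)
            except JCSaturationError:
                dist = 3.0   # conventional cap for saturated pairs
            d[i, j] = d[j, i] = dist
    return DistanceMatrix([r.id for r in records], d)


def nj_tree(matrix: DistanceMatrix) -> str:
    """Neighbor-joining tree as a newick string with branch lengths.

    Deterministic: the pair with the lowest Q is joined, ties broken by
    label order; negative branch lengths are clamped to zero.
    """
    n = len(matrix.labels)
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    labels = list(matrix.labels)          # newick fragments
    sort_keys = list(matrix.labels)       # deterministic tie-breaking
    d = matrix.d.astype(float).copy()
    while len(labels) > 3:
        m = len(labels)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (round(q, 12), min(sort_keys[i], sort_keys[j]),
                       max(sort_keys[i], sort_keys[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new_label = f"({labels[i]}:{li:.12g},{labels[j]}:{lj:.12g})"
        new_key = min(sort_keys[i], sort_keys[j])
        new_row = 0.5 * (d[i] + d[j] - dij)
        keep = [x for x in range(m) if x not in (i, j)]
        d_new = np.zeros((len(keep) + 1, len(keep) + 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = new_row[keep]
        d = d_new
        labels = [labels[x] for x in keep] + [new_label]
        sort_keys = [sort_keys[x] for x in keep] + [new_key]
    # final three-taxon star: branch lengths from the three pair equations
    (a, b, c) = range(3)
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    return (f"({labels[0]}:{la:.12g},{labels[1]}:{lb:.12g},"
            f"{labels[2]}:{lc:.12g});")


@dataclass(frozen=True)
class FamilyAssignment:
    gene_id: str
    family: str
    nearest_exemplar: str
    distance: float
    margin: float


# classification uses semi-global alignment with affine gaps: end gaps are
# free (a truncated gene scores cleanly against a full-length exemplar) and
# internal gaps are kept contiguous instead of being scattered to hide
# mismatches, which the linear-gap global aligner is free to do
_class_aligner = Align.PairwiseAligner()
_class_aligner.mode = "global"
_class_aligner.match_score = 1
_class_aligner.mismatch_score = -1
_class_aligner.open_gap_score = -4
_class_aligner.extend_gap_score = -0.5
_class_aligner.end_insertion_score = 0
_class_aligner.end_deletion_score = 0


def classification_distance(a: str, b: str, min_coverage: float = 0.8) -> float:
    """JC-style distance used for nearest-exemplar assignment.

    After semi-global alignment, terminal overhangs are ignored, and
    *internal* gap columns count as differences.  The aligned core must
    cover at least ``min_coverage`` of one of the two sequences (otherwise
    a trivial short overlap between unrelated sequences would score as
    near-identity).  Returns ``inf`` when the pair fails the coverage gate
    or the estimate is saturated (p >= 0.75).
    """
    aln = _class_aligner.align(a.upper(), b.upper())[0]
    ga, gb = str(aln[0]), str(aln[1])
    cols = list(zip(ga, gb))
    i0 = 0
    i1 = len(cols)
    while i0 < i1 and ("-" in cols[i0]):
        i0 += 1
    while i1 > i0 and ("-" in cols[i1 - 1]):
        i1 -= 1
    n = i1 - i0
    if n == 0:
        return math.inf
    core = cols[i0:i1]
    span_a = sum(1 for x, _ in core if x != "-")
    span_b = sum(1 for _, y in core if y != "-")
    if max(span_a / len(a), span_b / len(b)) < min_coverage:
        return math.inf
    diffs = sum(1 for x, y in core if x != y or "-" in (x, y))
    p = diffs / n
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) if p else 0.0


def assign_family(gene: SeqRecord,
                  exemplars: Sequence[tuple[str, SeqRecord]],
                  max_dist: float = 1.0) -> FamilyAssignment:
    """Assign a gene to the family of its JC-nearest exemplar.

    Distances come from :func:`classification_distance`; saturated pairs
    count as infinitely distant.  If the best distance exceeds ``max_dist``
    the gene is reported as "unclassified".  The margin is the gap to the
    best exemplar of the runner-up family.
    """
    if not exemplars:
        raise ValueError("exemplar set must be non-empty")
    per_family: dict[str, tuple[float, str]] = {}
    for family, ex in exemplars:
        dist = classification_distance(gene.sequence, ex.sequence)
        cur = per_family.get(family)
        if cur is None or dist < cur[0]:
            per_family[family] = (dist, ex.id)
    ranked = sorted((dist, family, ex_id)
                    for family, (dist, ex_id) in per_family.items())
    best_dist, best_family, best_ex = ranked[0]
    margin = (ranked[1][0] - best_dist) if len(ranked) > 1 else math.inf
    if not math.isfinite(margin):
        margin = 0.0 if not math.isfinite(best_dist) else margin
    if best_dist > max_dist:
        return FamilyAssignment(gene.id, "unclassified", best_ex,
                                best_dist if math.isfinite(best_dist) else 3.0,
                                margin if math.isfinite(margin) else 3.0)
    return FamilyAssignment(gene.id, best_family, best_ex, best_dist, margin)
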