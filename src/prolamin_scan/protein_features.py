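"""Gene status calling, avenin domain segmentation and composition tables.

Status calling works on the covered span of a locus consensus: the longest
ATG-initiated reading frame is translated, a stop before the terminal stop
marks a pseudogene, and short or start-less open reading frames are gene
fragments.  Avenin proteins are segmented into the canonical seven domains
(19-residue signal peptide, three conserved domains, two P/Q/L-rich
repetitive domains, C-terminal domain) from windowed P+Q+L content.
Composition tables report per-protein amino-acid frequency percentages with
half-up rounding, matching the formatting of published tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .io_core import translate
from .locus_consensus import ConsensusSequence

__all__ = [
    "GeneCall", "AveninDomains", "CompositionSummary", "call_gene",
    "count_cysteines", "segment_avenin", "composition_table",
    "summarize_composition", "load_published_composition",
    "AA_NAMES", "TOTAL_ROW",
]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

#: printed row names of the published composition table -> one-letter codes
AA_NAMES: dict[str, str] = {
    "Alanin": "A", "Cystein": "C", "Aspartic acid": "D", "Glutamic acid": "E",
    "Phenylalanin": "F", "Glycin": "G", "Histidin": "H", "Isoleucin": "I",
    "Lysin": "K", "Leucin": "L", "Methionin": "M", "Asparagin": "N",
    "Prolin": "P", "Glutamin": "Q", "Arginin": "R", "Serin": "S",
    "Threonin": "T", "Valin": "V", "Tryptofan": "W", "Tyrosin": "Y",
}

TOTAL_ROW = "total"


def _round_half_up(x: float | Decimal, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Gene status
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneCall:
    gene_id: str
    locus_id: str
    cds: str
    protein: str
    status: str          # whole | fragment | pseudogene
    family: str = ""
    cds_start: int = 0   # position of the ATG within the consensus


def _covered_span(consensus: ConsensusSequence, min_depth: int,
                  max_uncovered: int) -> tuple[int, int] | None:
    """Widest well-covered region, tolerating short internal gaps (introns)."""
    covered = [i for i, d in enumerate(consensus.depth) if d >= min_depth]
    if not covered:
        return None
    # split where gaps exceed max_uncovered, keep the largest block
    blocks: list[list[int]] = [[covered[0], covered[0]]]
    for pos in covered[1:]:
        if pos - blocks[-1][1] - 1 > max_uncovered:
            blocks.append([pos, pos])
        else:
            blocks[-1][1] = pos
    s, e = max(blocks, key=lambda b: (b[1] - b[0], -b[0]))
    return s, e + 1


def call_gene(consensus: ConsensusSequence, family_hint: str = "",
              min_gene_len: int = 300, min_depth: int = 3,
              max_uncovered: int = 200) -> GeneCall:
    """Call gene status from a locus consensus.

    The search is restricted to the read-covered span (so reference flanks
    never contribute); the first ATG opens the reading frame, the last
    in-frame stop terminates the CDS, and any earlier in-frame stop marks a
    pseudogene.  No ATG, or a CDS shorter than ``min_gene_len``, yields a
    fragment.
    """
    span = _covered_span(consensus, min_depth, max_uncovered)
    if span is None:
        return GeneCall(consensus.locus_id, consensus.locus_id, "", "",
                        "fragment", family_hint)
    region = consensus.sequence[span[0]:span[1]]
    atg = region.find("ATG")
    if atg < 0 or len(region) - atg < 3:
        return GeneCall(consensus.locus_id, consensus.locus_id, "", "",
                        "fragment", family_hint)
    frame = region[atg:]
    aa = translate(frame)
    stop_positions = [i for i, r in enumerate(aa) if r == "*"]
    if not stop_positions:
        cds = frame[: len(aa) * 3]
        protein = aa
        internal = []
    else:
        last = stop_positions[-1]
        cds = frame[: (last + 1) * 3]
        internal = stop_positions[:-1]
        protein = aa[: stop_positions[0]]
    status = "whole"
    if internal:
        status = "pseudogene"
    elif len(cds) < min_gene_len:
        status = "fragment"
    return GeneCall(consensus.locus_id, consensus.locus_id, cds, protein,
                    status, family_hint, span[0] + atg)


def count_cysteines(protein: str) -> int:
    if not protein:
        raise ValueError("empty protein")
    return protein.count("C")


# ---------------------------------------------------------------------------
# Avenin domain segmentation
# ---------------------------------------------------------------------------

SIGNAL_PEPTIDE_LEN = 19

_DOMAIN_NAMES = (
    "signal_peptide", "conserved1", "repetitive1", "conserved2",
    "repetitive2", "conserved3", "c_terminal",
)


@dataclass
class AveninDomains:
    segments: dict[str, tuple[int, int]]
    failed: bool = False
    n_repetitive_found: int = 2

    def boundaries(self) -> list[tuple[int, int]]:
        return [self.segments[n] for n in _DOMAIN_NAMES]


def segment_avenin(protein: str, family: str = "",
                   rep_threshold: float = 0.55, min_rep_len: int = 15,
                   window: int = 9, cterm_len: int = 15) -> AveninDomains:
    """Segment an avenin protein into its seven canonical domains.

    The signal peptide is the first 19 residues by definition; the two
    repetitive domains are maximal runs where windowed P+Q+L content reaches
    ``rep_threshold`` (run length >= ``min_rep_len``); conserved domains and
    the fixed-length C-terminal domain fill the remainder in order.  If the
    repetitive structure is not recovered (e.g. one giant repeat region) the
    result carries a segmentation-failure flag.
    """
    n = len(protein)
    if n < 60:
        raise ValueError("protein too short to segment (< 60 residues)")
    flags = [1 if r in "PQL" else 0 for r in protein]
    half = window // 2
    frac = []
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        frac.append(sum(flags[lo:hi]) / (hi - lo))
    lo_lim = SIGNAL_PEPTIDE_LEN
    hi_lim = n - cterm_len
    rep_mask = [lo_lim <= i < hi_lim and frac[i] >= rep_threshold
                for i in range(n)]
    raw: list[tuple[int, int]] = []
    i = lo_lim
    while i < hi_lim:
        if rep_mask[i]:
            j = i
            while j < hi_lim and rep_mask[j]:
                j += 1
            raw.append((i, j))
            i = j
        else:
            i += 1
    # bridge 1-3 residue dips (epitope heads are slightly less P/Q/L-rich
    # than the tandem repeats that follow them), then apply the length floor
    merged: list[tuple[int, int]] = []
    for s, e in raw:
        if merged and s - merged[-1][1] <= 3:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    runs = [(s, e) for s, e in merged if e - s >= min_rep_len]
    segments = {"signal_peptide": (0, SIGNAL_PEPTIDE_LEN)}
    if len(runs) != 2:
        segments["repetitive_runs"] = runs  # type: ignore[assignment]
        return AveninDomains(segments, failed=True, n_repetitive_found=len(runs))
    (r1s, r1e), (r2s, r2e) = runs
    segments.update({
        "conserved1": (SIGNAL_PEPTIDE_LEN, r1s),
        "repetitive1": (r1s, r1e),
        "conserved2": (r1e, r2s),
        "repetitive2": (r2s, r2e),
        "conserved3": (r2e, n - cterm_len),
        "c_terminal": (n - cterm_len, n),
    })
    return AveninDomains(segments)


# ---------------------------------------------------------------------------
# Composition tables
# ---------------------------------------------------------------------------


def composition_table(proteins: Sequence[tuple[str, str]],
                      exclude_signal: bool = False,
                      signal_len: int = SIGNAL_PEPTIDE_LEN) -> pd.DataFrame:
    """Amino-acid frequency percentages (2 decimals, half-up) per protein.

    Rows: the 20 amino acids (one-letter) plus a ``total`` row with the
    residue count.  By default the signal peptide is included, matching the
    published totals; set ``exclude_signal`` to profile mature proteins.
    """
    if not proteins:
        raise ValueError("no proteins given")
    data: dict[str, list[float]] = {}
    for label, protein in proteins:
        if exclude_signal:
            protein = protein[signal_len:]
        if not protein:
            raise ValueError(f"empty protein {label!r}")
        col = [_round_half_up(100.0 * protein.count(aa) / len(protein), 2)
               for aa in AA_ORDER]
        col.append(len(protein))
        if label in data:
            raise ValueError(f"duplicate column label {label!r}")
        data[label] = col
    return pd.DataFrame(data, index=list(AA_ORDER) + [TOTAL_ROW])


def load_published_composition() -> pd.DataFrame:
    """The published avenin composition table, shipped verbatim as a fixture.

    Columns are family.chromosome labels (A/B/C1/C2/D groups); rows are
    mapped from the printed amino-acid names to one-letter codes.
    """
    with resources.files("prolamin_scan.data").joinpath(
            "avenin_composition_published.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df.index = [AA_NAMES.get(name, TOTAL_ROW) for name in df.index]
    return df


@dataclass
class CompositionSummary:
    table: pd.DataFrame          # rows (group, amino_acid) -> min, max, mean
    mean_length: int

    def cell(self, group: str, aa: str) -> tuple[float, float, float]:
        row = self.table.loc[(group, aa)]
        return float(row["min"]), float(row["max"]), float(row["mean"])


def summarize_composition(table: pd.DataFrame,
                          groups: Mapping[str, Sequence[str]]
                          ) -> CompositionSummary:
    """Per-group min/max/mean of each amino-acid frequency.

    Ranges are reported to 1 decimal and means to 2 decimals (half-up,
    matching the published formatting); the mean protein length over *all*
    table columns is rounded to the nearest integer.
    """
    unknown = {c for cols in groups.values() for c in cols} - set(table.columns)
    if unknown:
        raise ValueError(f"unknown group column(s) {sorted(unknown)}")
    rows = []
    for group, cols in groups.items():
        sub = table.loc[[aa for aa in AA_ORDER], list(cols)]
        for aa in AA_ORDER:
            vals = [Decimal(str(v)) for v in sub.loc[aa]]
            rows.append({
                "group": group, "amino_acid": aa,
                "min": _round_half_up(min(vals), 1),
                "max": _round_half_up(max(vals), 1),
                "mean": _round_half_up(sum(vals) / len(vals), 2),
            })
    summary = pd.DataFrame(rows).set_index(["group", "amino_acid"])
    lengths = [Decimal(str(v)) for v in table.loc[TOTAL_ROW]]
    mean_length = int(_round_half_up(sum(lengths) / len(lengths), 0))
    return CompositionSummary(summary, mean_length)
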