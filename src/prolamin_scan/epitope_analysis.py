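"""Celiac-disease T-cell epitope scanning and haploid copy-number accounting.

The bundled definitions cover the HLA-DQ2.5-restricted avenin epitopes
(ave-1a/1b/1c/2, with the observed oat variant forms) and the tandem 9-mer
PFVQQQQPF (Av-gamma9B).  Matching is exact against the canonical form or an
explicitly listed variant — the observed forms are enumerated, not found by
fuzzy search — and overlapping occurrences all count, which matters for the
tandem PFVQQQQPF repeats.  Per-protein occurrence counts are converted to
copies per haploid genome through the family-level gene inventory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io_core import SeqRecord

__all__ = [
    "EpitopeDefinition", "EpitopeMatch", "HaplotypeCount",
    "default_epitopes", "scan_epitopes", "count_haplotype",
    "position_incidence", "load_epitope_definitions",
    "write_epitope_definitions", "demo_reference_epitopes",
]


@dataclass(frozen=True)
class EpitopeDefinition:
    name: str
    canonical: str
    variants: tuple[str, ...] = ()
    restricted_families: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.name or not self.canonical:
            raise ValueError("epitope name and canonical sequence required")
        for v in self.variants:
            if len(v) != len(self.canonical):
                raise ValueError(
                    f"{self.name}: variant {v} length differs from canonical")

    def forms(self) -> tuple[str, ...]:
        return (self.canonical,) + self.variants


def default_epitopes() -> list[EpitopeDefinition]:
    """The avenin epitope set: canonical forms plus observed oat variants."""
    return [
        EpitopeDefinition("DQ2.5-ave-1a", "PYPEQQEPF",
                          restricted_families=frozenset({"avenin-C2"})),
        EpitopeDefinition("DQ2.5-ave-1b", "PYPEQEQPF", ("PYPEQQQPF",),
                          frozenset({"avenin-C1"})),
        EpitopeDefinition("DQ2.5-ave-1c", "PYPEQEQPI", ("PYPEQQQPI",),
                          frozenset({"avenin-B"})),
        EpitopeDefinition("DQ2.5-ave-2", "PYPEQQPF",
                          restricted_families=frozenset({"avenin-A"})),
        EpitopeDefinition("Av-gamma9B", "PFVQQQQPF",
                          restricted_families=frozenset({"avenin-C2"})),
    ]


@dataclass(frozen=True)
class EpitopeMatch:
    protein_id: str
    epitope: str
    matched: str
    start: int
    is_variant: bool


def scan_epitopes(protein: SeqRecord | str,
                  defs: Sequence[EpitopeDefinition] | None = None
                  ) -> list[EpitopeMatch]:
    """All occurrences (overlaps included) of each epitope form, by position.

    An empty protein yields an empty list, not an error.
    """
    if defs is None:
        defs = default_epitopes()
    if not defs:
        raise ValueError("epitope definition list must be non-empty")
    if isinstance(protein, str):
        protein = SeqRecord("protein", protein) if protein else None
        if protein is None:
            return []
    seq = protein.sequence
    matches: list[EpitopeMatch] = []
    for d in defs:
        for form in d.forms():
            start = seq.find(form)
            while start != -1:
                matches.append(EpitopeMatch(protein.id, d.name, form, start,
                                            form != d.canonical))
                start = seq.find(form, start + 1)
    return sorted(matches, key=lambda m: (m.start, m.epitope, m.matched))


@dataclass(frozen=True)
class HaplotypeCount:
    epitope: str
    copies_per_protein: Mapping[str, int]   # family -> copies per protein
    inventory: Mapping[str, int]            # family -> gene count
    total: int
    consistent: bool = True
    per_gene: Mapping[str, int] = field(default_factory=dict)


def count_haplotype(matches_by_protein: Mapping[str, tuple[str, Sequence[EpitopeMatch]]],
                    inventory: Mapping[str, int],
                    defs: Sequence[EpitopeDefinition] | None = None
                    ) -> list[HaplotypeCount]:
    """Convert per-protein epitope occurrences to copies per haploid genome.

    ``matches_by_protein`` maps protein id -> (family label, matches).  The
    per-protein copy number must be uniform within a family; if it is not,
    the modal value is used, the count is flagged inconsistent and the
    per-gene occurrence table is attached.  Total copies =
    sum over families of copies_per_protein x gene count.
    """
    if defs is None:
        defs = default_epitopes()
    unknown = {family for family, _ in matches_by_protein.values()
               } - set(inventory)
    if unknown:
        raise ValueError(f"families missing from inventory: {sorted(unknown)}")
    out = []
    for d in defs:
        per_gene: dict[str, int] = {}
        by_family: dict[str, list[int]] = {}
        for pid, (family, matches) in matches_by_protein.items():
            n = sum(1 for m in matches if m.epitope == d.name)
            per_gene[pid] = n
            by_family.setdefault(family, []).append(n)
        copies: dict[str, int] = {}
        consistent = True
        for family, counts in by_family.items():
            if len(set(counts)) > 1:
                consistent = False
                counts = sorted(counts)
                copies[family] = max(set(counts), key=counts.count)
            else:
                copies[family] = counts[0]
        total = sum(copies.get(family, 0) * count
                    for family, count in inventory.items())
        out.append(HaplotypeCount(d.name, copies, dict(inventory), total,
                                  consistent,
                                  per_gene if not consistent else {}))
    return out


def position_incidence(query: str, reference_set: Sequence[str]
                       ) -> list[tuple[int, str, float]]:
    """Per-position incidence of the query residue in a reference epitope set.

    References must be padded/aligned to the query length ('-' allowed);
    gaps are excluded from the denominator at their position.
    """
    if not reference_set:
        raise ValueError("reference epitope set must be non-empty")
    for ref in reference_set:
        if len(ref) != len(query):
            raise ValueError("reference epitopes must be aligned to the query "
                             f"length ({len(query)}): got {ref!r}")
    out = []
    for i, residue in enumerate(query):
        informative = [ref[i] for ref in reference_set if ref[i] != "-"]
        if informative:
            inc = sum(1 for r in informative if r == residue) / len(informative)
        else:
            inc = 0.0
        out.append((i, residue, inc))
    return out


# ---------------------------------------------------------------------------
# TSV interface for user-supplied definitions; bundled demo reference set
# ---------------------------------------------------------------------------


def write_epitope_definitions(defs: Sequence[EpitopeDefinition],
                              path: str | Path) -> None:
    lines = ["name\tcanonical\tvariants\tfamilies"]
    for d in defs:
        lines.append("\t".join([
            d.name, d.canonical, ";".join(d.variants),
            ";".join(sorted(d.restricted_families))]))
    Path(path).write_text("\n".join(lines) + "\n")


def load_epitope_definitions(path: str | Path) -> list[EpitopeDefinition]:
    defs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["name", "canonical"]:
            raise ValueError(f"unexpected epitope TSV header in {path}")
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            name, canonical = fields[0], fields[1]
            variants = tuple(v for v in fields[2].split(";") if v) \
                if len(fields) > 2 else ()
            families = frozenset(f for f in fields[3].split(";") if f) \
                if len(fields) > 3 else frozenset()
            defs.append(EpitopeDefinition(name, canonical, variants, families))
    return defs


def demo_reference_epitopes() -> list[tuple[str, str]]:
    """A small synthetic demo set of P/Q-rich 9-mers for incidence profiling.

    This is NOT the published wheat/barley/rye epitope registry (which is
    not reproduced here); supply your own aligned set for real comparisons.
    """
    return [
        ("demo-glia-like-1", "PFPQPQQPF"),
        ("demo-glia-like-2", "PQPQQPFPQ"),
        ("demo-glut-like-1", "PFSQQQQPV"),
        ("demo-glut-like-2", "PYSQQQQPF"),
        ("demo-hor-like-1", "PFPQQPQQF"),
        ("demo-sec-like-1", "PQQQFPQQQ"),
    ]
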