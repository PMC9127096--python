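"""Synthetic genome / transcript / long-read generator with ground truth.

The default genome model emulates the storage-protein landscape of a
hexaploid oat: three avenin cassettes (chr1D: C1-B-C2-A; chr3D: two D genes
and a fragment followed by promoter-C1-B-C2-C2-A; chrUn:
fragment-D-C1-B-C2-C2-fragment-A), globulin loci on chr3D/1A/1D/7A/Un and
AATI loci on chr4A/4C/4D/7C/1D.  Every planted element is recorded in a
machine-readable truth table (locus, family, status, domain boundaries,
planted epitope copy numbers) so each pipeline stage can be validated by a
direct round trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import families as fam
from .io_core import GenomicInterval, SeqRecord, reverse_complement

__all__ = [
    "CassetteSpec", "GenomeModel", "VarietyProfile", "TruthLocus",
    "TruthTable", "ReadSimConfig", "default_genome_model",
    "default_profile", "build_genome", "simulate_transcripts",
    "simulate_reads",
]

#: constant amplification/selection termini carried by every transcript
TRANSCRIPT_5P = "GACTGCGTACC"
TRANSCRIPT_3P = "GATC" + "A" * 20

_ELEMENT_LABELS = frozenset(fam.ALL_FAMILIES) | {"promoter", "fragment"}


@dataclass(frozen=True)
class CassetteSpec:
    """An ordered run of storage-protein genes on one chromosome."""

    chromosome: str
    gene_order: tuple[str, ...]
    spacing_bp: int = 2000
    start: int | None = None

    def __post_init__(self) -> None:
        if not self.gene_order:
            raise ValueError("gene_order must be non-empty")
        unknown = set(self.gene_order) - _ELEMENT_LABELS
        if unknown:
            raise ValueError(f"unknown gene labels {sorted(unknown)}")
        if self.spacing_bp < 0:
            raise ValueError("spacing_bp must be non-negative")


@dataclass(frozen=True)
class GenomeModel:
    chromosomes: tuple[tuple[str, int], ...]
    cassettes: tuple[CassetteSpec, ...]
    intergenic_gc: float = 0.45
    pseudogenize: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValueError("chromosome names must be unique")
        if not 0.0 <= self.intergenic_gc <= 1.0:
            raise ValueError("intergenic_gc must be in [0, 1]")
        known = set(names)
        for cas in self.cassettes:
            if cas.chromosome not in known:
                raise ValueError(f"cassette on unknown chromosome {cas.chromosome}")

    def chromosome_length(self, name: str) -> int:
        for c, length in self.chromosomes:
            if c == name:
                return length
        raise KeyError(name)


@dataclass(frozen=True)
class VarietyProfile:
    """Variety-level presence/absence and C2 tandem-repeat dosage."""

    name: str = "reference"
    absent_genes: frozenset[str] = frozenset()
    c2_repeat_count: int = 3

    def __post_init__(self) -> None:
        if self.c2_repeat_count not in (2, 3):
            raise ValueError("c2_repeat_count must be 2 or 3")


@dataclass(frozen=True)
class TruthLocus:
    gene_id: str
    interval: GenomicInterval
    family: str
    status: str                       # whole | fragment | pseudogene
    introns: tuple[tuple[int, int], ...] = ()   # relative to the locus
    cds: str = ""                     # spliced CDS incl. stop ('' for non-genes)
    protein: str = ""                 # translation product ('' for non-genes)


@dataclass
class TruthTable:
    loci: list[TruthLocus]
    epitope_counts: dict[str, int]
    domain_boundaries: dict[str, dict[str, tuple[int, int]]]
    variety: str = "reference"
    c2_repeat_count: int = 3

    def by_family(self) -> dict[str, list[TruthLocus]]:
        out: dict[str, list[TruthLocus]] = {}
        for row in self.loci:
            out.setdefault(row.family, []).append(row)
        return out

    def gene_inventory(self) -> dict[str, int]:
        """family -> number of intact (whole) gene copies per haploid genome."""
        inv: dict[str, int] = {}
        for row in self.loci:
            if row.status == "whole":
                inv[row.family] = inv.get(row.family, 0) + 1
        return inv

    def to_tsv(self) -> str:
        lines = ["gene_id\tchrom\tstart\tend\tstrand\tfamily\tstatus"]
        for row in self.loci:
            iv = row.interval
            lines.append(f"{row.gene_id}\t{iv.chromosome}\t{iv.start}\t{iv.end}"
                         f"\t{iv.strand}\t{row.family}\t{row.status}")
        return "\n".join(lines) + "\n"

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        (outdir / "truth_loci.tsv").write_text(self.to_tsv())
        (outdir / "truth_epitopes.json").write_text(
            json.dumps({"variety": self.variety,
                        "c2_repeat_count": self.c2_repeat_count,
                        "epitope_counts": self.epitope_counts}, indent=2) + "\n")
        (outdir / "truth_domains.json").write_text(
            json.dumps(self.domain_boundaries, indent=2) + "\n")


@dataclass(frozen=True)
class ReadSimConfig:
    n_reads: int
    mean_length: float = 1027.0
    length_sd: float = 120.0
    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        for name in ("substitution_rate", "insertion_rate", "deletion_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 0.2:
                raise ValueError(f"{name} must be in [0, 0.2]")


def default_genome_model() -> GenomeModel:
    """The study-like desk-scale genome (printed cassette orders)."""
    return GenomeModel(
        chromosomes=(
            ("chr1A", 15000), ("chr1D", 30000), ("chr3D", 45000),
            ("chr4A", 12000), ("chr4C", 9000), ("chr4D", 9000),
            ("chr7A", 9000), ("chr7C", 9000), ("chrUn", 40000),
        ),
        cassettes=(
            CassetteSpec("chr1A", ("globulin-A", "globulin-B")),
            CassetteSpec("chr1D", ("avenin-C1", "avenin-B", "avenin-C2", "avenin-A")),
            CassetteSpec("chr1D", ("globulin-C",)),
            CassetteSpec("chr1D", ("AATI-3",)),
            CassetteSpec("chr3D", ("avenin-D", "fragment", "avenin-D", "promoter",
                                   "avenin-C1", "avenin-B", "avenin-C2",
                                   "avenin-C2", "avenin-A")),
            CassetteSpec("chr3D", ("globulin-A", "globulin-D")),
            CassetteSpec("chr4A", ("AATI-1", "AATI-3")),
            CassetteSpec("chr4C", ("AATI-2",)),
            CassetteSpec("chr4D", ("AATI-unknown",)),
            CassetteSpec("chr7A", ("globulin-B",)),
            CassetteSpec("chr7C", ("AATI-2",)),
            CassetteSpec("chrUn", ("fragment", "avenin-D", "avenin-C1", "avenin-B",
                                   "avenin-C2", "avenin-C2", "fragment", "avenin-A")),
            CassetteSpec("chrUn", ("globulin-D",)),
        ),
    )


def default_profile(name: str = "reference", absent_b_on_3d: bool = False,
                    c2_repeat_count: int = 3) -> VarietyProfile:
    """Convenience profiles; the reduced-B profile drops avenin-B on chr3D."""
    absent = frozenset({"chr3D.avenin-B.1"}) if absent_b_on_3d else frozenset()
    return VarietyProfile(name, absent, c2_repeat_count)


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------


def _element_sequence(label: str, copy_index: int, profile: VarietyProfile
                      ) -> tuple[str, tuple[tuple[int, int], ...], str, str]:
    """Return (genomic sequence, introns, spliced CDS, protein) for one element."""
    if label.startswith("avenin-"):
        cds = fam.avenin_cds(label, copy_index, profile.c2_repeat_count)
        protein, _ = fam.avenin_protein(label, profile.c2_repeat_count)
        return cds, (), cds, protein
    if label.startswith("globulin-"):
        genomic, introns = fam.globulin_genomic_cds(label, copy_index)
        spliced = fam.globulin_spliced_cds(label, copy_index)
        return genomic, tuple(introns), spliced, fam.globulin_protein(label)
    if label.startswith("AATI-"):
        cds = fam.aati_cds(label, copy_index)
        return cds, (), cds, fam.aati_protein(label)
    if label == "fragment":
        seq = fam.fragment_cds(copy_index)
        return seq, (), seq, ""
    if label == "promoter":
        return fam.PROMOTER_SEQ, (), fam.PROMOTER_SEQ, ""
    raise ValueError(f"unknown element label {label!r}")


def _pseudogenize(genomic: str, spliced: str, introns) -> tuple[str, str, str]:
    """Plant an internal stop mid-CDS; returns new (genomic, spliced, protein)."""
    n_codons = len(spliced) // 3
    target = (n_codons // 2) * 3
    new_spliced = spliced[:target] + fam.STOP_CODON + spliced[target + 3:]
    from .io_core import translate
    protein = translate(new_spliced)
    truncated = protein.split("*")[0]
    if not introns:
        return new_spliced, new_spliced, truncated
    # map the spliced codon position into the genomic copy
    shift = 0
    pos = target
    for (s, e) in introns:
        if s <= pos + shift:
            shift += e - s
    g = genomic[:target + shift] + fam.STOP_CODON + genomic[target + shift + 3:]
    return g, new_spliced, truncated


def _intergenic(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def build_genome(model: GenomeModel | None = None,
                 profile: VarietyProfile | None = None,
                 seed: int = 0) -> tuple[list[SeqRecord], TruthTable]:
    """Build the synthetic genome and its truth table.

    Same (model, profile, seed) reproduces byte-identical FASTA output.
    """
    model = model or default_genome_model()
    profile = profile or VarietyProfile()

    # enumerate planted elements with stable ids and per-family copy indices
    placements: list[tuple[str, str, str, int]] = []  # (chrom, label, gene_id, copy)
    copy_counter: dict[str, int] = {}
    id_counter: dict[tuple[str, str], int] = {}
    all_ids: set[str] = set()
    for cas in model.cassettes:
        for label in cas.gene_order:
            copy = copy_counter.get(label, 0)
            copy_counter[label] = copy + 1
            ordinal = id_counter.get((cas.chromosome, label), 0) + 1
            id_counter[(cas.chromosome, label)] = ordinal
            gene_id = f"{cas.chromosome}.{label}.{ordinal}"
            all_ids.add(gene_id)
            placements.append((cas.chromosome, label, gene_id, copy))

    missing = profile.absent_genes - all_ids
    if missing:
        raise ValueError(f"absent_genes not in model: {sorted(missing)}")
    missing_pseudo = set(model.pseudogenize) - all_ids
    if missing_pseudo:
        raise ValueError(f"pseudogenize ids not in model: {sorted(missing_pseudo)}")

    # lay out elements chromosome by chromosome
    rng = np.random.default_rng(seed)
    loci: list[TruthLocus] = []
    domains: dict[str, dict[str, tuple[int, int]]] = {}
    chrom_parts: dict[str, list[str]] = {c: [] for c, _ in model.chromosomes}
    cursor: dict[str, int] = {c: 0 for c, _ in model.chromosomes}
    placement_idx = 0
    for cas in model.cassettes:
        chrom = cas.chromosome
        if cas.start is not None:
            if cas.start < cursor[chrom]:
                raise ValueError(
                    f"cassette start {cas.start} overlaps previous cassette on {chrom}")
            pad = cas.start - cursor[chrom]
            chrom_parts[chrom].append(_intergenic(rng, pad, model.intergenic_gc))
            cursor[chrom] += pad
        for label in cas.gene_order:
            chrom_, label_, gene_id, copy = placements[placement_idx]
            placement_idx += 1
            assert chrom_ == chrom and label_ == label
            if gene_id in profile.absent_genes:
                continue
            genomic, introns, spliced, protein = _element_sequence(
                label, copy, profile)
            status = "whole" if protein else "fragment"
            if gene_id in model.pseudogenize:
                genomic, spliced, protein = _pseudogenize(genomic, spliced, introns)
                status = "pseudogene"
            gap = cas.spacing_bp
            chrom_parts[chrom].append(_intergenic(rng, gap, model.intergenic_gc))
            start = cursor[chrom] + gap
            end = start + len(genomic)
            if end > model.chromosome_length(chrom):
                raise ValueError(
                    f"{gene_id} extends past the end of {chrom} "
                    f"({end} > {model.chromosome_length(chrom)})")
            chrom_parts[chrom].append(genomic)
            cursor[chrom] = end
            loci.append(TruthLocus(gene_id, GenomicInterval(chrom, start, end, "+"),
                                   label, status, introns, spliced, protein))
            if label.startswith("avenin-") and status == "whole":
                domains[gene_id] = fam.avenin_protein(
                    label, profile.c2_repeat_count)[1]

    records = []
    for chrom, length in model.chromosomes:
        tail = length - cursor[chrom]
        chrom_parts[chrom].append(_intergenic(rng, tail, model.intergenic_gc))
        records.append(SeqRecord(chrom, "".join(chrom_parts[chrom])))

    # planted epitope copies per haploid inventory (intact genes only)
    inventory: dict[str, int] = {}
    for row in loci:
        if row.status == "whole":
            inventory[row.family] = inventory.get(row.family, 0) + 1
    epitope_counts: dict[str, int] = {}
    for name, per_family in fam.PLANTED_EPITOPES.items():
        total = 0
        for family, per_protein in per_family.items():
            copies = profile.c2_repeat_count if per_protein is None else per_protein
            total += copies * inventory.get(family, 0)
        epitope_counts[name] = total

    truth = TruthTable(loci, epitope_counts, domains,
                       variety=profile.name,
                       c2_repeat_count=profile.c2_repeat_count)
    return records, truth


# ---------------------------------------------------------------------------
# Transcripts and reads
# ---------------------------------------------------------------------------


def simulate_transcripts(genome: Sequence[SeqRecord], truth: TruthTable
                         ) -> list[SeqRecord]:
    """One transcript per planted element; globulin introns are spliced out.

    Transcripts carry the constant amplification terminus at the 5' end and a
    poly-A tail at the 3' end, so enrichment-probe motifs are present on the
    coding strand.  Pseudogenes are transcribed as well (transcription
    ignores reading frame).
    """
    by_name = {rec.id: rec.sequence for rec in genome}
    out = []
    for row in truth.loci:
        iv = row.interval
        genomic = by_name[iv.chromosome][iv.start:iv.end]
        if row.introns:
            keep = []
            prev = 0
            for s, e in row.introns:
                keep.append(genomic[prev:s])
                prev = e
            keep.append(genomic[prev:])
            spliced = "".join(keep)
        else:
            spliced = genomic
        out.append(SeqRecord(f"{row.gene_id}.mRNA",
                             TRANSCRIPT_5P + spliced + TRANSCRIPT_3P,
                             description=f"family={row.family} status={row.status}"))
    return out


_BASES = "ACGT"


def _apply_errors(seq: str, cfg: ReadSimConfig, rng: np.random.Generator) -> str:
    p_sub, p_ins, p_del = (cfg.substitution_rate, cfg.insertion_rate,
                           cfg.deletion_rate)
    if p_sub == p_ins == p_del == 0.0:
        return seq
    out = []
    u = rng.random(len(seq))
    for i, base in enumerate(seq):
        if u[i] < p_sub:
            out.append(_BASES[(("ACGT".index(base) if base in _BASES else 0)
                               + 1 + rng.integers(3)) % 4])
        elif u[i] < p_sub + p_ins:
            out.append(base)
            out.append(_BASES[rng.integers(4)])
        elif u[i] < p_sub + p_ins + p_del:
            continue
        else:
            out.append(base)
    return "".join(out)


def simulate_reads(transcripts: Sequence[SeqRecord], cfg: ReadSimConfig
                   ) -> list[SeqRecord]:
    """Sample noisy single-end long reads uniformly over transcripts.

    Read lengths are Normal(mean_length, length_sd), truncated to the source
    transcript length (and to a 50 bp floor); about half of the reads are
    reverse-complemented.  The source span is recorded in the description.
    """
    if not transcripts:
        raise ValueError("cannot simulate reads from an empty transcript set")
    rng = np.random.default_rng(cfg.seed)
    reads = []
    for i in range(cfg.n_reads):
        t = transcripts[rng.integers(len(transcripts))]
        tlen = len(t.sequence)
        length = int(round(rng.normal(cfg.mean_length, cfg.length_sd)))
        length = max(50, min(length, tlen))
        start = int(rng.integers(0, tlen - length + 1))
        fragment = t.sequence[start:start + length]
        fragment = _apply_errors(fragment, cfg, rng)
        strand = "+"
        if rng.random() < 0.5:
            fragment = reverse_complement(fragment)
            strand = "-"
        reads.append(SeqRecord(
            f"read{i:06d}", fragment,
            description=f"src={t.id} start={start} end={start + length} "
                        f"strand={strand}"))
    return reads
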