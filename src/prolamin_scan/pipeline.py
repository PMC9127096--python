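"""End-to-end pipeline: simulate -> map -> loci -> consensus -> classify ->
features -> epitopes -> report.

Every stage writes its intermediates to the output directory so each step
is independently inspectable and resumable, and a rerun with the same
configuration and seed reproduces byte-identical outputs.  Synthetic mode
generates the genome and reads itself; real mode consumes a user-supplied
reference FASTA and read FASTQ.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from . import families as fam
from .epitope_analysis import (count_haplotype, default_epitopes,
                               load_epitope_definitions, scan_epitopes)
from .io_core import (GenomicInterval, SeqRecord, format_fasta, read_fasta,
                      read_fastq, reverse_complement, write_bed, write_fasta,
                      write_fastq)
from .locus_consensus import (anchor_read_to_reference, call_consensus,
                              extract_reduced_reference, merge_loci)
from .mapping import index_reference, map_read, read_alignments, write_alignments
from .phylo import (assign_family, distance_matrix_from_sequences, nj_tree)
from .protein_features import call_gene, composition_table, count_cysteines, segment_avenin
from .synthetic_data import (ReadSimConfig, build_genome, default_genome_model,
                             default_profile, simulate_reads, simulate_transcripts)

logger = logging.getLogger("prolamin_scan")

__all__ = ["PipelineConfig", "PipelineError", "RunReport", "validate_config",
           "run_all", "run_stage", "STAGES"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


_RANGES: dict[str, tuple[float, float]] = {
    "max_occ": (1, 10_000), "max_gap": (1, 100_000), "min_anchors": (1, 1000),
    "min_span": (1, 100_000), "min_reads": (1, 100_000), "flank": (0, 10_000),
    "min_depth": (1, 100_000), "min_alt_fraction": (0.0, 1.0),
    "min_gene_len": (3, 100_000), "rep_threshold": (0.0, 1.0),
    "max_dist": (0.0, 10.0), "n_reads": (1, 10_000_000),
    "mean_length": (50, 100_000), "length_sd": (0, 10_000),
    "substitution_rate": (0.0, 0.2), "insertion_rate": (0.0, 0.2),
    "deletion_rate": (0.0, 0.2), "c2_repeat_count": (2, 3),
}


@dataclass
class PipelineConfig:
    mode: str = "synthetic"            # synthetic | real
    reference: str | None = None       # real mode: genome FASTA
    reads: str | None = None           # real mode: FASTQ
    exemplars: str | None = None       # optional FASTA "family|name" ids
    epitopes: str | None = None        # optional TSV of epitope definitions
    outdir: str = "pipeline_out"
    seed: int = 0
    # synthetic generator
    n_reads: int = 1200
    mean_length: float = 1027.0
    length_sd: float = 120.0
    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    c2_repeat_count: int = 3
    absent_genes: tuple[str, ...] = ()
    variety: str = "reference"
    # mapping
    k: int = 15
    max_occ: int = 50
    max_gap: int = 500
    min_anchors: int = 3
    min_span: int = 100
    # loci / consensus
    min_reads: int = 3
    flank: int = 50
    min_depth: int = 3
    min_alt_fraction: float = 0.2
    # features / classification
    min_gene_len: int = 300
    rep_threshold: float = 0.55
    max_dist: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError(f"mode must be synthetic or real, not {self.mode!r}")
        if self.k % 2 == 0 or not 11 <= self.k <= 21:
            raise ValueError("k must be odd in [11,21]")
        for name, (lo, hi) in _RANGES.items():
            value = getattr(self, name)
            if not lo <= value <= hi:
                raise ValueError(f"{name}={value} outside [{lo}, {hi}]")
        if self.mode == "real":
            if not self.reference:
                raise ValueError("real mode requires a reference path")
            if not self.reads:
                raise ValueError("real mode requires a reads path")
        self.absent_genes = tuple(self.absent_genes)

    def config_hash(self) -> str:
        # the output location does not influence the science: two runs that
        # differ only in outdir must produce identical reports
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        return hashlib.sha256(json.dumps(payload, sort_keys=True,
                                         default=str).encode()).hexdigest()[:16]


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and range-check a YAML config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return PipelineConfig(**raw)


@dataclass
class RunReport:
    version: str
    config_hash: str
    seed: int
    n_reads_total: int = 0
    n_reads_mapped: int = 0
    n_loci: int = 0
    genes_by_family: dict[str, dict[str, int]] = field(default_factory=dict)
    status_counts: dict[str, int] = field(default_factory=dict)
    composition: dict[str, dict[str, float]] = field(default_factory=dict)
    epitope_totals: dict[str, int] = field(default_factory=dict)
    inventory: dict[str, int] = field(default_factory=dict)
    tree_file: str = ""

    def validate(self) -> None:
        if self.n_reads_mapped > self.n_reads_total:
            raise ValueError("mapped reads exceed total reads")
        n_genes = sum(sum(v.values()) for v in self.genes_by_family.values())
        if n_genes > self.n_loci:
            raise ValueError("more genes than loci")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"


# ---------------------------------------------------------------------------
# Stages (each reads its inputs from, and writes its outputs to, outdir)
# ---------------------------------------------------------------------------


def _out(config: PipelineConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _log(stage: str, message: str, out: Path) -> None:
    logger.info("[%s] %s", stage, message)
    with open(out / "pipeline_log.jsonl", "a") as fh:
        fh.write(json.dumps({"stage": stage, "message": message}) + "\n")


def stage_simulate(config: PipelineConfig) -> None:
    out = _out(config)
    if config.mode != "synthetic":
        raise PipelineError("simulate", "simulate stage requires synthetic mode")
    profile = default_profile(config.variety,
                              c2_repeat_count=config.c2_repeat_count)
    profile = dataclasses.replace(profile,
                                  absent_genes=frozenset(config.absent_genes))
    try:
        genome, truth = build_genome(default_genome_model(), profile,
                                     config.seed)
    except ValueError as exc:
        raise PipelineError("simulate", str(exc)) from exc
    transcripts = simulate_transcripts(genome, truth)
    reads = simulate_reads(transcripts, ReadSimConfig(
        config.n_reads, config.mean_length, config.length_sd,
        config.substitution_rate, config.insertion_rate,
        config.deletion_rate, config.seed))
    write_fasta(genome, out / "genome.fasta")
    write_fasta(transcripts, out / "transcripts.fasta")
    write_fastq(reads, out / "reads.fastq")
    truth.write(out)
    _log("simulate", f"{len(genome)} chromosomes, {len(truth.loci)} planted "
         f"loci, {len(reads)} reads", out)


def _load_reference_and_reads(config: PipelineConfig
                              ) -> tuple[list[SeqRecord], list[SeqRecord]]:
    out = _out(config)
    if config.mode == "synthetic":
        ref_path, reads_path = out / "genome.fasta", out / "reads.fastq"
    else:
        ref_path, reads_path = Path(config.reference), Path(config.reads)
    if not ref_path.exists() or not reads_path.exists():
        raise PipelineError("map", f"missing inputs ({ref_path}, {reads_path}); "
                            "run the simulate stage first or set paths")
    return read_fasta(ref_path), read_fastq(reads_path)


def stage_map(config: PipelineConfig) -> None:
    out = _out(config)
    genome, reads = _load_reference_and_reads(config)
    if not reads:
        raise PipelineError("map", "no reads to map")
    index = index_reference(genome, config.k, config.max_occ)
    alignments = [map_read(r, index, config.max_gap, config.min_anchors,
                           config.min_span) for r in reads]
    write_alignments(alignments, out / "alignments_genome.tsv")
    n_mapped = sum(a.mapped for a in alignments)
    _log("map", f"{n_mapped}/{len(reads)} reads mapped to the reference", out)


def stage_loci(config: PipelineConfig) -> None:
    out = _out(config)
    alignments = read_alignments(out / "alignments_genome.tsv")
    genome, _ = _load_reference_and_reads(config)
    loci = merge_loci(alignments, config.min_reads)
    if not loci:
        raise PipelineError("loci", "no loci passed the read-support filter")
    write_bed([l.interval for l in loci], out / "loci.bed",
              names=[l.locus_id for l in loci])
    reduced = extract_reduced_reference(genome, loci, config.flank)
    write_fasta(reduced, out / "reduced_reference.fasta")
    _log("loci", f"{len(loci)} merged loci", out)


def stage_consensus(config: PipelineConfig) -> None:
    out = _out(config)
    reduced = read_fasta(out / "reduced_reference.fasta")
    _, reads = _load_reference_and_reads(config)
    index = index_reference(reduced, config.k, config.max_occ)
    realigned = [map_read(r, index, config.max_gap, config.min_anchors,
                          config.min_span) for r in reads]
    write_alignments(realigned, out / "alignments_reduced.tsv")
    grouped: dict[str, list[str]] = {}
    for read, aln in zip(reads, realigned):
        if aln.mapped and aln.target is not None:
            seq = (read.sequence if aln.target.strand == "+"
                   else reverse_complement(read.sequence))
            grouped.setdefault(aln.target.chromosome, []).append(seq)
    consensus_records = []
    depth_lines = []
    variant_lines = ["locus\tpos\tref\talt\tfraction"]
    for rec in reduced:
        placements = [anchor_read_to_reference(s, rec.sequence, config.k)
                      for s in grouped.get(rec.id, [])]
        cons = call_consensus(placements, rec, config.min_depth,
                              config.min_alt_fraction)
        flag = " low_confidence" if cons.low_confidence else ""
        consensus_records.append(SeqRecord(rec.id, cons.sequence,
                                           description=rec.description + flag))
        depth_lines.append(rec.id + "\t" +
                           ",".join(str(d) for d in cons.depth))
        for pos, ref, alt, fraction in cons.variants:
            variant_lines.append(f"{rec.id}\t{pos}\t{ref}\t{alt}\t{fraction:.4f}")
    write_fasta(consensus_records, out / "consensus.fasta")
    (out / "consensus_depth.tsv").write_text("\n".join(depth_lines) + "\n")
    (out / "variants.tsv").write_text("\n".join(variant_lines) + "\n")
    _log("consensus", f"{len(consensus_records)} consensus sequences, "
         f"{len(variant_lines) - 1} variants", out)


def _load_exemplars(config: PipelineConfig) -> list[tuple[str, SeqRecord]]:
    if config.exemplars:
        records = read_fasta(config.exemplars)
        out = []
        for rec in records:
            family = rec.id.split("|")[0]
            out.append((family, rec))
        return out
    return [(family, SeqRecord(f"{family}|exemplar", seq,
                               description="synthetic stand-in"))
            for family, seq in fam.exemplar_sequences()]


def stage_classify(config: PipelineConfig) -> None:
    out = _out(config)
    consensus = read_fasta(out / "consensus.fasta")
    exemplars = _load_exemplars(config)
    lines = ["gene_id\tfamily\tnearest_exemplar\tdistance\tmargin"]
    for rec in consensus:
        asn = assign_family(rec, exemplars, config.max_dist)
        lines.append(f"{asn.gene_id}\t{asn.family}\t{asn.nearest_exemplar}"
                     f"\t{asn.distance:.6f}\t{asn.margin:.6f}")
    (out / "assignments.tsv").write_text("\n".join(lines) + "\n")
    if len(consensus) >= 3:
        tree = nj_tree(distance_matrix_from_sequences(consensus))
        (out / "tree.nwk").write_text(tree + "\n")
    _log("classify", f"{len(consensus)} sequences assigned", out)


def _read_assignments(out: Path) -> dict[str, str]:
    assignments = {}
    with open(out / "assignments.tsv") as fh:
        fh.readline()
        for line in fh:
            gene_id, family = line.split("\t")[:2]
            assignments[gene_id] = family
    return assignments


def stage_features(config: PipelineConfig) -> None:
    out = _out(config)
    consensus = read_fasta(out / "consensus.fasta")
    depth_by_id = {}
    with open(out / "consensus_depth.tsv") as fh:
        for line in fh:
            locus_id, depths = line.rstrip("\n").split("\t")
            depth_by_id[locus_id] = [int(x) for x in depths.split(",")]
    assignments = _read_assignments(out)
    from .locus_consensus import ConsensusSequence
    gene_lines = ["gene_id\tfamily\tstatus\tcds_len\tprotein_len\tn_cysteines"]
    domain_lines = ["gene_id\t" + "\t".join(
        f"{n}_start\t{n}_end" for n in (
            "signal_peptide", "conserved1", "repetitive1", "conserved2",
            "repetitive2", "conserved3", "c_terminal"))]
    avenin_proteins = []
    calls = []
    for rec in consensus:
        cons = ConsensusSequence(rec.id, rec.sequence, depth_by_id[rec.id], [])
        family = assignments.get(rec.id, "unclassified")
        call = call_gene(cons, family, config.min_gene_len, config.min_depth)
        calls.append(call)
        n_cys = count_cysteines(call.protein) if call.protein else 0
        gene_lines.append(f"{rec.id}\t{family}\t{call.status}\t{len(call.cds)}"
                          f"\t{len(call.protein)}\t{n_cys}")
        if family.startswith("avenin") and call.status == "whole":
            avenin_proteins.append((rec.id, call.protein))
            domains = segment_avenin(call.protein, family,
                                     config.rep_threshold)
            if not domains.failed:
                domain_lines.append(rec.id + "\t" + "\t".join(
                    f"{s}\t{e}" for s, e in domains.boundaries()))
    (out / "gene_calls.tsv").write_text("\n".join(gene_lines) + "\n")
    (out / "avenin_domains.tsv").write_text("\n".join(domain_lines) + "\n")
    if avenin_proteins:
        table = composition_table(avenin_proteins)
        table.to_csv(out / "avenin_composition.tsv", sep="\t")
    _log("features", f"{len(calls)} gene calls, "
         f"{len(avenin_proteins)} whole avenins", out)


def stage_epitopes(config: PipelineConfig) -> None:
    out = _out(config)
    defs = (load_epitope_definitions(config.epitopes) if config.epitopes
            else default_epitopes())
    assignments = _read_assignments(out)
    matches_by_protein = {}
    inventory: dict[str, int] = {}
    match_lines = ["protein_id\tepitope\tmatched\tstart\tis_variant"]
    with open(out / "gene_calls.tsv") as fh:
        fh.readline()
        gene_rows = [line.rstrip("\n").split("\t") for line in fh]
    consensus = read_fasta(out / "consensus.fasta")
    depth_by_id = {}
    with open(out / "consensus_depth.tsv") as fh:
        for line in fh:
            locus_id, depths = line.rstrip("\n").split("\t")
            depth_by_id[locus_id] = [int(x) for x in depths.split(",")]
    from .locus_consensus import ConsensusSequence
    proteins = {}
    for rec in consensus:
        cons = ConsensusSequence(rec.id, rec.sequence, depth_by_id[rec.id], [])
        call = call_gene(cons, "", config.min_gene_len, config.min_depth)
        proteins[rec.id] = call.protein
    for gene_id, family, status, *_ in gene_rows:
        if not family.startswith("avenin") or status != "whole":
            continue
        inventory[family] = inventory.get(family, 0) + 1
        matches = scan_epitopes(SeqRecord(gene_id, proteins[gene_id]), defs)
        matches_by_protein[gene_id] = (family, matches)
        for m in matches:
            match_lines.append(f"{m.protein_id}\t{m.epitope}\t{m.matched}"
                               f"\t{m.start}\t{m.is_variant}")
    (out / "epitope_matches.tsv").write_text("\n".join(match_lines) + "\n")
    counts = count_haplotype(matches_by_protein, inventory, defs)
    payload = {
        "inventory": inventory,
        "per_haplotype": {h.epitope: h.total for h in counts},
        "copies_per_protein": {h.epitope: dict(h.copies_per_protein)
                               for h in counts},
        "consistent": {h.epitope: h.consistent for h in counts},
    }
    (out / "epitope_report.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n")
    _log("epitopes", f"totals {payload['per_haplotype']}", out)


def stage_report(config: PipelineConfig) -> RunReport:
    out = _out(config)
    reads = read_fastq(out / "reads.fastq") if config.mode == "synthetic" \
        else read_fastq(config.reads)
    alignments = read_alignments(out / "alignments_genome.tsv")
    with open(out / "gene_calls.tsv") as fh:
        fh.readline()
        gene_rows = [line.rstrip("\n").split("\t") for line in fh]
    genes_by_family: dict[str, dict[str, int]] = {}
    status_counts: dict[str, int] = {}
    for _, family, status, *_ in gene_rows:
        genes_by_family.setdefault(family, {})
        genes_by_family[family][status] = genes_by_family[family].get(status, 0) + 1
        status_counts[status] = status_counts.get(status, 0) + 1
    epitope_payload = json.loads((out / "epitope_report.json").read_text())
    composition: dict[str, dict[str, float]] = {}
    comp_path = out / "avenin_composition.tsv"
    if comp_path.exists():
        import pandas as pd
        table = pd.read_csv(comp_path, sep="\t", index_col=0)
        for aa in ("P", "Q", "L"):
            composition[aa] = {
                "min": float(table.loc[aa].min()),
                "max": float(table.loc[aa].max()),
            }
    report = RunReport(
        version=__version__,
        config_hash=config.config_hash(),
        seed=config.seed,
        n_reads_total=len(reads),
        n_reads_mapped=sum(a.mapped for a in alignments),
        n_loci=len(gene_rows),
        genes_by_family=genes_by_family,
        status_counts=status_counts,
        composition=composition,
        epitope_totals=epitope_payload["per_haplotype"],
        inventory=epitope_payload["inventory"],
        tree_file="tree.nwk" if (out / "tree.nwk").exists() else "",
    )
    report.validate()
    (out / "report.json").write_text(report.to_json())
    _log("report", f"report written ({report.n_loci} loci)", out)
    return report


STAGES = {
    "simulate": stage_simulate,
    "map": stage_map,
    "loci": stage_loci,
    "consensus": stage_consensus,
    "classify": stage_classify,
    "features": stage_features,
    "epitopes": stage_epitopes,
    "report": stage_report,
}


def run_stage(name: str, config: PipelineConfig):
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}")
    try:
        return STAGES[name](config)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc


def run_all(config: PipelineConfig) -> RunReport:
    """Run every stage in order and return the final report."""
    names = list(STAGES)
    if config.mode == "real":
        names.remove("simulate")
    report = None
    for name in names:
        report = run_stage(name, config)
    assert isinstance(report, RunReport)
    return report
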