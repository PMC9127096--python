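"""Shared fixtures: a default synthetic genome and full pipeline runs.

Pipeline runs are session-scoped because they take ~20 s each; the noise
conditions (read depth ~35x, 2% substitution) are the recovery conditions
the pipeline is specified to handle exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import pytest

from prolamin_scan.pipeline import PipelineConfig, run_all
from prolamin_scan.synthetic_data import build_genome, simulate_transcripts


@pytest.fixture(scope="session")
def genome_truth():
    return build_genome(seed=1)


@pytest.fixture(scope="session")
def genome(genome_truth):
    return genome_truth[0]


@pytest.fixture(scope="session")
def truth(genome_truth):
    return genome_truth[1]


@pytest.fixture(scope="session")
def transcripts(genome_truth):
    return simulate_transcripts(*genome_truth)


def _run_pipeline(outdir: Path, substitution_rate: float, seed: int):
    config = PipelineConfig(outdir=str(outdir), seed=seed, n_reads=1200,
                            substitution_rate=substitution_rate)
    report = run_all(config)
    return config, report


@pytest.fixture(scope="session")
def pipeline_clean(tmp_path_factory):
    """Full pipeline run on noise-free reads (seed 7)."""
    outdir = tmp_path_factory.mktemp("pipeline_clean")
    return outdir, *_run_pipeline(outdir, 0.0, 7)


@pytest.fixture(scope="session")
def pipeline_noisy(tmp_path_factory):
    """Full pipeline run at 2% substitution noise (seed 11)."""
    outdir = tmp_path_factory.mktemp("pipeline_noisy")
    return outdir, *_run_pipeline(outdir, 0.02, 11)


@pytest.fixture(scope="session")
def pipeline_clean_repeat(tmp_path_factory):
    """Second noise-free run with the same seed, for determinism checks."""
    outdir = tmp_path_factory.mktemp("pipeline_clean_repeat")
    return outdir, *_run_pipeline(outdir, 0.0, 7)


def locus_map(outdir: Path, truth):
    """Map each truth gene_id to the reduced-reference locus containing it."""
    from prolamin_scan.io_core import read_fasta

    reduced = read_fasta(outdir / "reduced_reference.fasta")
    spans = {}
    for rec in reduced:
        chrom, coords = rec.description.split(":")
        s, e = (int(x) for x in coords.split("-"))
        spans[rec.id] = (chrom, s, e)
    mapping = {}
    for row in truth.loci:
        iv = row.interval
        hits = [locus_id for locus_id, (chrom, s, e) in spans.items()
                if chrom == iv.chromosome and s <= iv.start and iv.end <= e]
        mapping[row.gene_id] = hits
    return mapping
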