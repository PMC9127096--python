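"""Shared configuration for the numbered analysis scripts.

The study conditions: ~5,000 long reads (mean 1,027 nt) at 2% substitution
noise over the default hexaploid-like genome, giving roughly 150x coverage
per planted locus.  All scripts share one output directory so each stage
picks up the previous stage's intermediates.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from prolamin_scan.pipeline import PipelineConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def study_config(seed: int = 1, outdir: str | None = None) -> PipelineConfig:
    out = outdir or str(SCRATCH / "pipeline")
    return PipelineConfig(outdir=out, seed=seed, n_reads=5000,
                          substitution_rate=0.02)


def parse_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", default=None)
    return parser.parse_args()
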