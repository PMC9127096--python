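#!/usr/bin/env python
"""Merge mapped intervals into loci, reduce the reference, call consensus."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import parse_args, study_config

from prolamin_scan.pipeline import run_stage


def main() -> None:
    args = parse_args(__doc__)
    config = study_config(args.seed, args.outdir)
    run_stage("loci", config)
    run_stage("consensus", config)
    out = Path(config.outdir)
    n_loci = len(out.joinpath("loci.bed").read_text().strip().splitlines())
    n_variants = len(out.joinpath("variants.tsv").read_text()
                     .strip().splitlines()) - 1
    print(f"{n_loci} merged loci; consensus called with {n_variants} "
          f"variant columns against the reduced reference")
    print("(at 2% read noise the majority pileup should cancel essentially "
          "all errors; a non-zero variant count would indicate residual "
          "mis-anchoring)")


if __name__ == "__main__":
    main()
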