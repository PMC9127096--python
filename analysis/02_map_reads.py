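#!/usr/bin/env python
"""Map the simulated long reads to the synthetic genome (k-mer chaining)."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import parse_args, study_config

from prolamin_scan.mapping import read_alignments
from prolamin_scan.pipeline import run_stage


def main() -> None:
    args = parse_args(__doc__)
    config = study_config(args.seed, args.outdir)
    run_stage("map", config)
    alignments = read_alignments(Path(config.outdir) / "alignments_genome.tsv")
    mapped = [a for a in alignments if a.mapped]
    identity = sum(a.identity_estimate for a in mapped) / len(mapped)
    print(f"{len(mapped)}/{len(alignments)} reads mapped "
          f"({100 * len(mapped) / len(alignments):.1f}%), "
          f"mean anchor identity {identity:.3f}")


if __name__ == "__main__":
    main()
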