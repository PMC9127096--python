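#!/usr/bin/env python
"""Assign consensus genes to families by JC distance to exemplars + NJ tree."""

import sys
from collections import Counter
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import parse_args, study_config

from prolamin_scan.pipeline import run_stage


def main() -> None:
    args = parse_args(__doc__)
    config = study_config(args.seed, args.outdir)
    run_stage("classify", config)
    out = Path(config.outdir)
    counts: Counter = Counter()
    with open(out / "assignments.tsv") as fh:
        fh.readline()
        for line in fh:
            counts[line.split("\t")[1]] += 1
    print("family assignments of consensus loci:")
    for family, n in sorted(counts.items()):
        print(f"  {family:<14s} {n}")
    print(f"neighbor-joining tree written to {out / 'tree.nwk'}")


if __name__ == "__main__":
    main()
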