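#!/usr/bin/env python
"""Score pathway and disease gene sets by their fraction of affected genes.

For each collection and each affected-gene flag (per significance class and
expression), computes per-set fractions over the analysis universe and the
headline summary: mean fraction and how many sets are affected for at least
25% / 50% of their genes.
"""

import argparse
from pathlib import Path

from txcontext.pipeline import AnalysisConfig, run_all


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--bundle", type=Path, default=Path("results/bundle"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = AnalysisConfig.from_dir(args.bundle, seed=args.seed)
    cfg.networks = {}
    report = run_all(cfg)
    report.write(args.out / "burden")

    for cname, block in sorted(report.sections["burden"].items()):
        print(f"{cname}:")
        for flag in ("transcript_PATHOGENIC", "expression"):
            if flag not in block:
                continue
            b = block[flag]
            print(
                f"  {flag:<22} mean fraction {100 * b['mean_fraction']:5.1f}%  "
                f">=25%: {b['count_ge_25']}/{b['n_scored']} sets  "
                f">=50%: {b['count_ge_50']}/{b['n_scored']} sets"
            )
    print(f"per-set table written to {args.out}/burden/burden.tsv")


if __name__ == "__main__":
    main()
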