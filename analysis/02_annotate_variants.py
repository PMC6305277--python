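#!/usr/bin/env python
"""Annotate every cohort variant against every transcript of its gene.

Reads the bundle from results/bundle/, classifies each assertion record,
annotates the retained variants per transcript (biotype-whitelisted), and
writes the flat per-(variant, transcript) consequence table to
results/annotation.tsv together with per-impact tallies.
"""

import argparse
from collections import Counter
from pathlib import Path

from txcontext.pipeline import AnalysisConfig, run_all


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--bundle", type=Path, default=Path("results/bundle"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = AnalysisConfig.from_dir(args.bundle, seed=args.seed)
    cfg.expression = cfg.samples = cfg.tx2gene = None
    cfg.gene_sets, cfg.networks = {}, {}
    report = run_all(cfg)
    report.write(args.out)

    impacts = Counter(call.impact.value for _, _, call in report.annotation_rows)
    total = sum(impacts.values())
    print(f"{total} consequence calls written to {args.out}/annotation.tsv")
    for impact in ("HIGH", "MODERATE", "LOW", "MODIFIER"):
        n = impacts.get(impact, 0)
        print(f"  {impact:<9} {n:6d}  ({100 * n / total:.1f}%)")


if __name__ == "__main__":
    main()
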