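#!/usr/bin/env python
"""Call F0 sperm DMRs (stress vs control) on the synthetic workspace.

Runs the smoothed beta-binomial Wald caller with the published thresholds
(site |delta beta| > 0.1 at FDR < 0.01; regions >= 50 bp, >= 4 DMCs,
post-filtered on |delta| >= 0.1 or >20% relative change) and reports how
many planted regions the calls recover.
"""

import argparse

import pandas as pd

from epiherit import pipeline


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results/workspace")
    args = ap.parse_args()
    cfg = pipeline.PipelineConfig(outdir=args.outdir, seed=args.seed)
    dmrs = pipeline.stage_calldmr(cfg)
    print(f"called {len(dmrs)} DMRs "
          f"({(dmrs['direction'] == 'hypo').mean():.0%} de-methylated)")
    truth = pd.read_csv(f"{args.outdir}/planted_truth.tsv", sep="\t")
    hit = sum(
        ((dmrs["chrom"] == r.chrom) & (dmrs["start"] < r.end)
         & (dmrs["end"] > r.start)).any()
        for r in truth.itertuples())
    print(f"planted regions recovered: {hit}/{len(truth)}")


if __name__ == "__main__":
    main()
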