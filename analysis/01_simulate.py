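#!/usr/bin/env python
"""Generate the synthetic study workspace.

Emulates the full design: 18 sperm methylomes (2 groups x 3 generations x
3 replicates) with planted transgenerational / intergenerational /
F0-only DMR classes, 12 embryo-stage profiles plus an oocyte, escape-prone
region sets, and a sperm sncRNA count table with planted fold changes.
Writes coverage files, sample sheet, BED region sets, FASTA and truth
tables under the workspace directory.
"""

import argparse

from epiherit import pipeline


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results/workspace")
    args = ap.parse_args()
    cfg = pipeline.PipelineConfig(outdir=args.outdir, seed=args.seed)
    sheet = pipeline.stage_simulate(cfg)
    print(f"wrote {len(sheet)} samples under {args.outdir}")
    print(sheet.groupby(["stage", "group"]).size())


if __name__ == "__main__":
    main()
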