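#!/usr/bin/env python
"""Classify F0 DMRs by cross-generation inheritance.

Per generation, a Welch t-test on the 3 v 3 replicate region levels with
BH adjustment and the |delta| >= 0.1 / relative > 0.2 effect rule decides
significance; the F0/F1/F2 pattern yields the transgenerational /
intergenerational / F0-only label.  The cross-generation signed-rank
route is written alongside for comparison.
"""

import argparse

from epiherit import pipeline


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results/workspace")
    args = ap.parse_args()
    cfg = pipeline.PipelineConfig(outdir=args.outdir, seed=args.seed)
    table, wil, summary = pipeline.stage_inherit(cfg)
    print(summary.to_string(index=False))
    agree = (table.sort_values("dmr_index")["label"].to_numpy()
             == wil.sort_values("dmr_index")["label"].to_numpy()).mean()
    print(f"t-test vs signed-rank route label agreement: {agree:.1%}")


if __name__ == "__main__":
    main()
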