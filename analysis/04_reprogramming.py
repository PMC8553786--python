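#!/usr/bin/env python
"""Reprogramming dynamics of DMRs across embryo stages.

Classifies each DMR against paternal sperm into the five base categories
(free/other-hypo, full/other-hyper, unchanged) in ICM, PS and PGC,
enumerates stress-vs-control trajectories over the three stages, runs the
per-category Fisher contrast between heritable and un-heritable DMRs, and
profiles erasure escape for TE / imprinted / VM-IAP region classes.
"""

import argparse

from epiherit import pipeline


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results/workspace")
    args = ap.parse_args()
    cfg = pipeline.PipelineConfig(outdir=args.outdir, seed=args.seed)
    cats, fisher, escape = pipeline.stage_reprogram(cfg)
    counts = (cats[cats["group"] == "stress"]
              .groupby(["stage", "category"]).size().unstack(fill_value=0))
    print("category counts (stress vs paternal sperm):")
    print(counts.to_string())
    print("\nheritable vs un-heritable Fisher p by stage (min over categories):")
    print(fisher.groupby("stage")["p"].min().to_string())
    if len(escape):
        print("\nescape (maintained fraction) at ICM by region class:")
        print(escape[escape["stage"] == "ICM"]
              .set_index("cls")["maintained"].round(3).to_string())


if __name__ == "__main__":
    main()
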