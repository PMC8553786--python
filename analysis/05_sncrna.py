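#!/usr/bin/env python
"""Differential sperm sncRNA enrichment and DMR seed matching.

Normalises counts to RPM, screens subclasses and unique sequences (sum of
counts > 15, sum of RPM > 1, Student t p < 0.05), summarises the
per-direction type composition, aligns differential sequences to DMR
sequences with a 7-bp seed window (direct + antisense), and compares the
alignment burden of heritable vs un-heritable DMRs.
"""

import argparse

from epiherit import pipeline


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results/workspace")
    args = ap.parse_args()
    cfg = pipeline.PipelineConfig(outdir=args.outdir, seed=args.seed)
    sub, seqs, comp, burden = pipeline.stage_sncrna(cfg)
    n_sub = int(sub["differential"].sum())
    n_seq = int(seqs["differential"].sum())
    print(f"differential subclasses: {n_sub}; differential sequences: {n_seq}")
    print(comp[comp["n"] > 0].to_string(index=False))
    if burden:
        print(f"\nalignment burden heritable={burden['mean_heritable']:.1f} "
              f"vs un-heritable={burden['mean_unheritable']:.1f} "
              f"(Mann-Whitney p={burden['p']:.2e})")


if __name__ == "__main__":
    main()
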