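"""Reusable study-scale experiments over synthetic data.

Each function sets up a planted design with :mod:`epiherit.synthetic`,
runs the corresponding analysis stage, and measures recovery or
calibration against the planted truth.  The analysis drivers, the test
suite and the acceptance script all call these, so the measured numbers
always come from the same code paths as a real run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import dmr_calling, heritability, meth_io, reprogramming, sncrna, synthetic

MIN_COVERAGE = 5


def _sperm_group(sim, gen, group, min_coverage=MIN_COVERAGE):
    out = []
    for r in (1, 2, 3):
        t = sim.samples[f"{gen}_{group}_rep{r}"]
        out.append(t[t["total"] >= min_coverage].reset_index(drop=True))
    return out


def call_f0_dmrs(sim):
    """Run the full caller on the F0 sperm samples of a simulation."""
    tabs = _sperm_group(sim, "F0", "control") + _sperm_group(sim, "F0", "stress")
    index, mC, total = meth_io.align_samples(tabs)
    return dmr_calling.call_dmrs(index, mC[:3], total[:3], mC[3:], total[3:])


def _overlaps(dmrs, row):
    return dmrs[
        (dmrs["chrom"] == row.chrom)
        & (dmrs["start"] < row.end)
        & (dmrs["end"] > row.start)
    ]


def null_calibration(seeds, n_sites: int = 100_000) -> dict:
    """Caller behaviour on pure-null methylomes (no planted signal).

    Returns the mean fraction of sites at FDR < 0.01, its standard error
    over seeds, and the mean called-DMR count per Mb.
    """
    fracs, rates = [], []
    for seed in seeds:
        sim = synthetic.simulate_methylomes(
            synthetic.null_config(seed=seed, n_sites=n_sites))
        tests, dmrs = call_f0_dmrs(sim)
        fracs.append(float((tests["fdr"] < 0.01).mean()))
        span_mb = sum(
            tests.groupby("chrom")["pos"].max() - tests.groupby("chrom")["pos"].min()
        ) / 1e6
        rates.append(len(dmrs) / span_mb)
    fracs = np.array(fracs)
    return {
        "site_fdr_fraction": float(fracs.mean()),
        "site_fdr_se": float(fracs.std(ddof=1) / np.sqrt(len(fracs)))
        if len(fracs) > 1 else 0.0,
        "dmrs_per_mb": float(np.mean(rates)),
        "n_sites": n_sites,
        "n_seeds": len(fracs),
    }


def recovery_experiment(seed: int = 1) -> dict:
    """Planted-DMR recovery and heritability label recovery.

    Simulates the full 18-sample design (100 transgenerational / 400
    intergenerational / 1,500 F0-only planted regions), calls F0 DMRs,
    classifies inheritance with both routes, and scores per-class
    sensitivity against the planted truth (a planted region counts as
    recovered when an overlapping called DMR carries its class label).
    """
    cfg = synthetic.SimConfig(
        seed=seed, n_te={}, n_vm_iap=0, n_vm_iap_variable=0,
        n_genes=0, n_imprinted=0, background_sites_per_chrom=5000,
    )
    sim = synthetic.simulate_methylomes(cfg)
    tests, dmrs = call_f0_dmrs(sim)
    truth = sim.truth

    levels, gen_means = {}, {}
    for gen in ("F0", "F1", "F2"):
        by = {}
        for group in ("control", "stress"):
            cols = [meth_io.region_levels(t, dmrs)[0]
                    for t in _sperm_group(sim, gen, group)]
            by[group] = np.column_stack(cols)
            gen_means[f"{group}_{gen}"] = np.nanmean(by[group], axis=1)
        levels[gen] = by
    gen_table = heritability.generation_table(levels)
    calls = heritability.classify_inheritance(gen_table)
    dmrs = dmrs.assign(
        label=calls.sort_values("dmr_index")["label"].to_numpy())
    wil = heritability.classify_inheritance_wilcoxon(pd.DataFrame(gen_means))
    agreement = float(
        (wil.sort_values("dmr_index")["label"].to_numpy()
         == dmrs["label"].to_numpy()).mean())

    recovered = np.array(
        [len(_overlaps(dmrs, r)) > 0 for r in truth.itertuples()])
    sens = {}
    for cls in ("transgenerational", "intergenerational", "F0_only"):
        sub = truth[truth["cls"] == cls]
        hits = [bool((_overlaps(dmrs, r)["label"] == cls).any())
                for r in sub.itertuples()]
        sens[cls] = float(np.mean(hits))

    # attenuation of |delta beta| over the heritable labels
    wide = gen_table.pivot(index="dmr_index", columns="generation",
                           values="delta_beta").abs()
    herit_mask = dmrs["label"].isin(
        ["transgenerational", "intergenerational"]).to_numpy()
    trend = heritability.delta_trend(wide[herit_mask][["F0", "F1", "F2"]])

    return {
        "n_planted": len(truth),
        "n_called": len(dmrs),
        "dmr_sensitivity": float(recovered.mean()),
        "label_sensitivity": sens,
        "route_agreement": agreement,
        "delta_trend": trend,
        "dmrs": dmrs,
        "truth": truth,
        "generation_table": gen_table,
    }


def reprogramming_experiment(
    seed: int = 1, n_runs: int = 20, n_per_arm: int = 300,
    ps_group_offset: float = 0.3,
) -> dict:
    """Heritable-vs-unheritable category contrasts across embryo stages.

    Each run plants erase-and-reestablish dynamics with a PS-only stress
    deficit on the heritable arm, classifies every region against sperm,
    and tests the per-category distributions with Fisher's exact test.
    Reported: fraction of runs with the qualitative pattern (PS contrast
    significant, ICM and PGC not).
    """
    ok, ps_sig, icm_sig, pgc_sig = 0, 0, 0, 0
    for run in range(n_runs):
        df = synthetic.simulate_reprogramming_arms(
            n_per_arm=n_per_arm, seed=seed * 1000 + run,
            ps_group_offset=ps_group_offset)
        sig = {}
        for stage in ("ICM", "PS", "PGC"):
            cats = {
                arm: reprogramming.classify_vs_sperm(
                    df.loc[df["arm"] == arm, "sperm"].to_numpy(),
                    df.loc[df["arm"] == arm, stage].to_numpy())
                for arm in ("heritable", "unheritable")
            }
            ft = reprogramming.compare_category_distributions(
                cats["heritable"], cats["unheritable"])
            sig[stage] = reprogramming.stage_contrast_significant(ft)
        ps_sig += sig["PS"]
        icm_sig += sig["ICM"]
        pgc_sig += sig["PGC"]
        ok += sig["PS"] and not sig["ICM"] and not sig["PGC"]
    return {
        "pattern_fraction": ok / n_runs,
        "ps_significant_fraction": ps_sig / n_runs,
        "icm_significant_fraction": icm_sig / n_runs,
        "pgc_significant_fraction": pgc_sig / n_runs,
        "n_runs": n_runs,
        "n_per_arm": n_per_arm,
    }


def sncrna_experiment(seed: int = 1, n_dmrs_per_arm: int = 100) -> dict:
    """Planted sncRNA design: recovery, composition, alignment burden."""
    herit = [f"h{i}" for i in range(n_dmrs_per_arm)]
    unherit = [f"u{i}" for i in range(n_dmrs_per_arm)]
    cfg = synthetic.SimConfig(seed=seed)
    table, fasta, truth = synthetic.simulate_sncrna(
        cfg, heritable_dmr_ids=herit, unheritable_dmr_ids=unherit)
    table = sncrna.rpm_normalize(table)
    seqs = sncrna.differential_sequences(table)
    planted = truth["planted"].notna().to_numpy()
    recovery = float(seqs["differential"].to_numpy()[planted].mean())
    sub = sncrna.differential_subclasses(table)
    comp = sncrna.composition_report(sub)
    diff = seqs[seqs["differential"]]
    matches = sncrna.match_all(
        {f"s{i}": s for i, s in enumerate(diff["sequence"])}, fasta)
    burden = sncrna.dmr_alignment_burden(matches, herit, unherit)
    return {
        "planted_recovery": recovery,
        "n_differential_sequences": int(len(diff)),
        "composition": comp,
        "burden_p": burden["p"],
        "burden_means": (burden["mean_heritable"], burden["mean_unheritable"]),
    }


def sncrna_null_rate(seed: int = 1) -> dict:
    """Fraction of tested sequences called differential under the null."""
    cfg = synthetic.SimConfig(seed=seed, n_planted={})
    table, _, _ = synthetic.simulate_sncrna(cfg)
    res = sncrna.differential_sequences(sncrna.rpm_normalize(table))
    tested = res[res["tested"]]
    return {
        "rate": float(tested["differential"].mean()),
        "n_tested": int(len(tested)),
    }
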