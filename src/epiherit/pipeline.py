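"""End-to-end orchestration over a workspace directory.

Each stage reads its inputs from the workspace written by earlier stages,
so stages can be rerun individually.  A manifest records the configuration
hash, seed and output files of every stage; identical configuration and
seed reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import dmr_calling, heritability, meth_io, reprogramming, sncrna, synthetic


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, defaulting to the published values."""

    outdir: str = "epiherit_out"
    seed: int = 0
    min_coverage: int = 5
    smooth_span_bp: int = 500
    dmc_effect_min: float = 0.1
    dmc_fdr_max: float = 0.01
    dmr_min_len: int = 50
    dmr_min_cpg: int = 4
    merge_gap_bp: int = 100
    postfilter_abs_min: float = 0.1
    postfilter_rel_min: float = 0.2
    generation_fdr_max: float = 0.01
    reprog_delta_min: float = 0.1
    reprog_free_max: float = 0.1
    reprog_full_min: float = 0.9
    high_level: float = 0.8
    vm_iap_sd_max: float = 0.1
    snc_count_min: int = 15
    snc_rpm_min: float = 1.0
    snc_p_max: float = 0.05
    seed_len: int = 7
    # synthetic run scale (the simulate stage)
    n_trans: int = 12
    n_inter: int = 40
    n_f0_only: int = 150
    background_sites: int = 4000

    def validate(self) -> None:
        if self.min_coverage < 0:
            raise ValueError("min_coverage must be non-negative")
        for name in ("dmc_fdr_max", "generation_fdr_max", "snc_p_max"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.dmr_min_len <= 0 or self.dmr_min_cpg <= 0:
            raise ValueError("DMR minimum length/CpG count must be positive")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _manifest_path(cfg):
    return os.path.join(cfg.outdir, "manifest.json")


def _update_manifest(cfg: PipelineConfig, stage: str, outputs: list[str]):
    path = _manifest_path(cfg)
    manifest = {}
    if os.path.exists(path):
        with open(path) as fh:
            manifest = json.load(fh)
    manifest.setdefault("config_hash", cfg.config_hash())
    manifest.setdefault("seed", cfg.seed)
    sums = {}
    for f in outputs:
        with open(f, "rb") as fh:
            sums[os.path.basename(f)] = hashlib.sha256(fh.read()).hexdigest()[:16]
    manifest.setdefault("stages", {})[stage] = sums
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _sim_config(cfg: PipelineConfig) -> synthetic.SimConfig:
    return synthetic.SimConfig(
        seed=cfg.seed,
        n_dmrs={
            "transgenerational": cfg.n_trans,
            "intergenerational": cfg.n_inter,
            "F0_only": cfg.n_f0_only,
        },
        background_sites_per_chrom=cfg.background_sites // 2,
    )


def stage_simulate(cfg: PipelineConfig):
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    sim = synthetic.simulate_methylomes(_sim_config(cfg))
    embryos, _ = synthetic.simulate_embryos(sim)
    sheet = synthetic.write_workspace(sim, cfg.outdir, embryos=embryos)
    herit = sim.truth[sim.truth["cls"].isin(
        ["transgenerational", "intergenerational"])]["region_id"].tolist()
    unherit = sim.truth[sim.truth["cls"] == "F0_only"]["region_id"].tolist()
    table, fasta, snc_truth = synthetic.simulate_sncrna(
        sim.config, heritable_dmr_ids=herit,
        unheritable_dmr_ids=unherit[: len(herit)],
    )
    table.to_csv(os.path.join(cfg.outdir, "sncrna_counts.tsv"),
                 sep="\t", index=False)
    snc_truth.to_csv(os.path.join(cfg.outdir, "sncrna_truth.tsv"),
                     sep="\t", index=False)
    meth_io.write_fasta(fasta, os.path.join(cfg.outdir, "dmr_seqs.fasta"))
    outputs = [os.path.join(cfg.outdir, f) for f in
               ["samples.tsv", "sncrna_counts.tsv", "dmr_seqs.fasta",
                "planted_truth.tsv", "regions.bed"]]
    _update_manifest(cfg, "simulate", outputs)
    return sheet


def _resolve(cfg: PipelineConfig, path: str) -> str:
    """Sample-sheet paths may be relative to the workspace directory."""
    return path if os.path.isabs(path) else os.path.join(cfg.outdir, path)


def _load_group(sheet: pd.DataFrame, cfg: PipelineConfig, **query):
    sel = sheet
    for k, v in query.items():
        sel = sel[sel[k] == v]
    return [
        meth_io.read_cytosine_report(_resolve(cfg, p),
                                     min_coverage=cfg.min_coverage)
        for p in sel.sort_values("replicate")["path"]
    ]


def stage_calldmr(cfg: PipelineConfig):
    sheet = meth_io.read_sample_sheet(os.path.join(cfg.outdir, "samples.tsv"))
    ctrl = _load_group(sheet, cfg, stage="sperm", generation="F0", group="control")
    strs = _load_group(sheet, cfg, stage="sperm", generation="F0", group="stress")
    index, mC, total = meth_io.align_samples(ctrl + strs)
    k = len(ctrl)
    tests, dmrs = dmr_calling.call_dmrs(
        index, mC[:k], total[:k], mC[k:], total[k:],
        span_bp=cfg.smooth_span_bp, effect_min=cfg.dmc_effect_min,
        fdr_max=cfg.dmc_fdr_max, min_len=cfg.dmr_min_len,
        min_cpg=cfg.dmr_min_cpg, merge_gap_bp=cfg.merge_gap_bp,
    )
    out = os.path.join(cfg.outdir, "dmrs.tsv")
    dmr_calling.write_dmrs(dmrs, out)
    regions_bed = os.path.join(cfg.outdir, "regions.bed")
    if os.path.exists(regions_bed):
        ann = dmr_calling.annotate_dmrs(dmrs, meth_io.read_regions(regions_bed))
        ann.to_csv(os.path.join(cfg.outdir, "dmr_annotation.tsv"),
                   sep="\t", index=False)
    _update_manifest(cfg, "calldmr", [out])
    return dmrs


def _region_levels_by_sample(sheet, cfg, regions, **query):
    sel = sheet
    for k, v in query.items():
        sel = sel[sel[k] == v]
    out = {}
    for r in sel.itertuples():
        counts = meth_io.read_cytosine_report(
            _resolve(cfg, r.path), min_coverage=cfg.min_coverage)
        levels, _ = meth_io.region_levels(counts, regions, kind="pooled")
        out[r.sample_id] = levels
    return out


def stage_inherit(cfg: PipelineConfig):
    sheet = meth_io.read_sample_sheet(os.path.join(cfg.outdir, "samples.tsv"))
    dmrs = dmr_calling.read_dmrs(os.path.join(cfg.outdir, "dmrs.tsv"))
    levels = {}
    gen_means_cols = {}
    for gen in ("F0", "F1", "F2"):
        by_group = {}
        for group in ("control", "stress"):
            reps = _region_levels_by_sample(
                sheet, cfg, dmrs, stage="sperm", generation=gen, group=group)
            by_group[group] = np.column_stack(list(reps.values()))
            gen_means_cols[f"{group}_{gen}"] = np.nanmean(
                by_group[group], axis=1)
        levels[gen] = by_group
    gen_table = heritability.generation_table(
        levels, fdr_max=cfg.generation_fdr_max)
    calls = heritability.classify_inheritance(gen_table)
    calls["dmr_id"] = dmrs["dmr_id"].to_numpy()[calls["dmr_index"]]
    wil = heritability.classify_inheritance_wilcoxon(
        pd.DataFrame(gen_means_cols))
    wil["dmr_id"] = dmrs["dmr_id"].to_numpy()[wil["dmr_index"].astype(int)]
    wide = gen_table.pivot(index="dmr_index", columns="generation",
                           values=["p", "fdr", "delta_beta"])
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    table = calls.merge(wide, left_on="dmr_index", right_index=True)
    out = os.path.join(cfg.outdir, "inheritance.tsv")
    table.to_csv(out, sep="\t", index=False)
    out_w = os.path.join(cfg.outdir, "inheritance_wilcoxon.tsv")
    wil.to_csv(out_w, sep="\t", index=False)
    summary = heritability.inheritance_summary(calls)
    summary.to_csv(os.path.join(cfg.outdir, "inheritance_summary.tsv"),
                   sep="\t", index=False)
    _update_manifest(cfg, "inherit", [out, out_w])
    return table, wil, summary


def stage_reprogram(cfg: PipelineConfig):
    sheet = meth_io.read_sample_sheet(os.path.join(cfg.outdir, "samples.tsv"))
    dmrs = dmr_calling.read_dmrs(os.path.join(cfg.outdir, "dmrs.tsv"))
    calls = pd.read_csv(os.path.join(cfg.outdir, "inheritance.tsv"), sep="\t")
    heritable = calls.loc[
        calls["label"].isin(["transgenerational", "intergenerational"]),
        "dmr_id"].tolist()
    rng = np.random.default_rng(cfg.seed + 11)
    unheritable = reprogramming.sample_unheritable(dmrs, heritable, rng)

    # paternal sperm reference: pooled F0 replicates per group
    sperm = {}
    for group in ("control", "stress"):
        reps = _region_levels_by_sample(
            sheet, cfg, dmrs, stage="sperm", generation="F0", group=group)
        sperm[group] = np.nanmean(np.column_stack(list(reps.values())), axis=1)

    cat_rows = []
    stage_deltas = {}
    fisher_tables = {}
    for stage in ("ICM", "PS", "PGC"):
        by_group = {}
        for group in ("control", "stress"):
            reps = _region_levels_by_sample(
                sheet, cfg, dmrs, stage=stage, generation="F1", group=group)
            if not reps:
                continue
            by_group[group] = next(iter(reps.values()))
            cats = reprogramming.classify_vs_sperm(
                sperm[group], by_group[group],
                delta_min=cfg.reprog_delta_min, free_max=cfg.reprog_free_max,
                full_min=cfg.reprog_full_min)
            for did, cat in zip(dmrs["dmr_id"], cats):
                cat_rows.append({"dmr_id": did, "stage": stage,
                                 "group": group, "category": cat})
        if {"control", "stress"} <= set(by_group):
            stage_deltas[stage] = by_group["stress"] - by_group["control"]
        cat_df = pd.DataFrame(cat_rows)
        here = cat_df[(cat_df["stage"] == stage) & (cat_df["group"] == "stress")]
        here = here.set_index("dmr_id")["category"]
        fisher_tables[stage] = reprogramming.compare_category_distributions(
            here.reindex(heritable), here.reindex(unheritable))

    cat_df = pd.DataFrame(cat_rows)
    cat_df.to_csv(os.path.join(cfg.outdir, "reprogramming_categories.tsv"),
                  sep="\t", index=False)
    traj, freq = reprogramming.enumerate_trajectories(
        pd.DataFrame(stage_deltas), delta_min=cfg.reprog_delta_min)
    traj.insert(0, "dmr_id", dmrs["dmr_id"])
    traj.to_csv(os.path.join(cfg.outdir, "trajectories.tsv"),
                sep="\t", index=False)
    freq.to_csv(os.path.join(cfg.outdir, "trajectory_patterns.tsv"),
                sep="\t", index=False)
    fish = pd.concat([t.assign(stage=s) for s, t in fisher_tables.items()])
    fish.to_csv(os.path.join(cfg.outdir, "category_fisher.tsv"),
                sep="\t", index=False)

    # escape profile over region classes
    esc_rows = []
    regions_bed = os.path.join(cfg.outdir, "regions.bed")
    if os.path.exists(regions_bed):
        regions = meth_io.read_regions(regions_bed)
        sperm_reg = {}
        for group in ("control",):
            reps = _region_levels_by_sample(
                sheet, cfg, regions, stage="sperm", generation="F0", group=group)
            sperm_reg = np.nanmean(np.column_stack(list(reps.values())), axis=1)
        for stage in ("ICM", "PS", "PGC"):
            reps = _region_levels_by_sample(
                sheet, cfg, regions, stage=stage, generation="F1",
                group="control")
            if not reps:
                continue
            emb = next(iter(reps.values()))
            for cls, idx in regions.groupby("cls").groups.items():
                prof = reprogramming.escape_profile(
                    sperm_reg[idx], emb[np.asarray(idx)],
                    high=cfg.high_level, delta_min=cfg.reprog_delta_min,
                    free_max=cfg.reprog_free_max)
                esc_rows.append({"cls": cls, "stage": stage, **prof})
        pd.DataFrame(esc_rows).to_csv(
            os.path.join(cfg.outdir, "escape_profile.tsv"),
            sep="\t", index=False)
    _update_manifest(cfg, "reprogram",
                     [os.path.join(cfg.outdir, "reprogramming_categories.tsv"),
                      os.path.join(cfg.outdir, "category_fisher.tsv")])
    return cat_df, fish, pd.DataFrame(esc_rows)


def stage_sncrna(cfg: PipelineConfig):
    table = sncrna.read_count_table(
        os.path.join(cfg.outdir, "sncrna_counts.tsv"))
    table = sncrna.rpm_normalize(table)
    sub = sncrna.differential_subclasses(
        table, count_min=cfg.snc_count_min, rpm_min=cfg.snc_rpm_min,
        p_max=cfg.snc_p_max)
    seqs = sncrna.differential_sequences(
        table, count_min=cfg.snc_count_min, rpm_min=cfg.snc_rpm_min,
        p_max=cfg.snc_p_max)
    comp = sncrna.composition_report(sub)
    sub.to_csv(os.path.join(cfg.outdir, "snc_subclasses.tsv"),
               sep="\t", index=False)
    seqs.to_csv(os.path.join(cfg.outdir, "snc_sequences.tsv"),
                sep="\t", index=False)
    comp.to_csv(os.path.join(cfg.outdir, "snc_composition.tsv"),
                sep="\t", index=False)

    fasta_path = os.path.join(cfg.outdir, "dmr_seqs.fasta")
    burden = {}
    if os.path.exists(fasta_path):
        dmr_seqs = meth_io.read_fasta(fasta_path)
        diff = seqs[seqs["differential"]]
        snc_seqs = {f"snc_{i}": s for i, s in enumerate(diff["sequence"])}
        matches = sncrna.match_all(snc_seqs, dmr_seqs, seed=cfg.seed_len)
        matches.to_csv(os.path.join(cfg.outdir, "seed_matches.tsv"),
                       sep="\t", index=False)
        truth_path = os.path.join(cfg.outdir, "planted_truth.tsv")
        if os.path.exists(truth_path):
            truth = pd.read_csv(truth_path, sep="\t")
            herit = truth[truth["cls"].isin(
                ["transgenerational", "intergenerational"])]["region_id"]
            herit = [d for d in herit if d in dmr_seqs]
            unherit = [d for d in dmr_seqs if d not in set(herit)]
            burden = sncrna.dmr_alignment_burden(matches, herit, unherit)
            pd.DataFrame({
                "dmr_id": list(herit) + list(unherit),
                "arm": ["heritable"] * len(herit) + ["unheritable"] * len(unherit),
                "burden": list(burden["burden_heritable"])
                + list(burden["burden_unheritable"]),
            }).to_csv(os.path.join(cfg.outdir, "alignment_burden.tsv"),
                      sep="\t", index=False)
    _update_manifest(cfg, "sncrna",
                     [os.path.join(cfg.outdir, "snc_subclasses.tsv"),
                      os.path.join(cfg.outdir, "snc_composition.tsv")])
    return sub, seqs, comp, burden


def make_report(cfg: PipelineConfig) -> dict:
    """Aggregate stage outputs into one summary dict (+ report.json)."""
    out = {}
    def maybe(name, fn):
        path = os.path.join(cfg.outdir, name)
        if os.path.exists(path):
            out[fn] = pd.read_csv(path, sep="\t")

    maybe("dmrs.tsv", "dmrs")
    maybe("inheritance_summary.tsv", "inheritance_summary")
    maybe("category_fisher.tsv", "category_fisher")
    maybe("trajectory_patterns.tsv", "trajectory_patterns")
    maybe("snc_composition.tsv", "snc_composition")
    report = {
        "n_dmrs": int(len(out.get("dmrs", []))),
        "inheritance": out.get("inheritance_summary", pd.DataFrame()).to_dict(
            orient="records"),
        "top_trajectories": out.get("trajectory_patterns", pd.DataFrame())
        .head(5).to_dict(orient="records"),
        "snc_composition": out.get("snc_composition", pd.DataFrame()).to_dict(
            orient="records"),
        "fisher_by_stage": {
            s: g.drop(columns="stage").to_dict(orient="records")
            for s, g in out.get(
                "category_fisher", pd.DataFrame(columns=["stage"])
            ).groupby("stage")
        },
    }
    with open(os.path.join(cfg.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    _update_manifest(cfg, "report", [os.path.join(cfg.outdir, "report.json")])
    return report


STAGES = {
    "simulate": stage_simulate,
    "calldmr": stage_calldmr,
    "inherit": stage_inherit,
    "reprogram": stage_reprogram,
    "sncrna": stage_sncrna,
    "report": make_report,
}


def run_pipeline(cfg: PipelineConfig, stages=None) -> dict:
    """Execute the requested stages in order; defaults to all of them."""
    cfg.validate()
    for name in stages or list(STAGES):
        if name not in STAGES:
            raise ValueError(f"unknown stage {name!r}")
        STAGES[name](cfg)
    with open(_manifest_path(cfg)) as fh:
        return json.load(fh)
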