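"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates the study design end to end: 18 sperm methylomes
(two groups x three generations x three replicates) with planted DMR
classes, embryo-stage profiles following the two waves of methylation
erasure and reestablishment, escape-prone region classes, and a sperm
sncRNA count table with planted subclass-specific fold changes plus DMR
sequences carrying embedded sncRNA complements.

Model choices:

* CpG coverage is Poisson; methylated counts are beta-binomial with a
  common dispersion, matching the caller's model assumptions exactly.
* Sperm baseline levels are bimodal (mass near 0 and above 0.8), in
  block-constant domains so that local smoothing is well specified.
* Planted DMR classes shift the stress-group mean by a fixed effect,
  attenuated per generation; the shift direction always points away from
  the nearer boundary (high baselines lose methylation, which also makes
  de-methylated DMRs the majority, as in real sperm).
* Planted heritable candidate regions are CpG-island-scale blocks (3 kb at
  1 CpG / 10 bp).  At 20x coverage the replicate-level region estimate has
  a counting-noise floor of roughly 0.02 / sqrt(K/30); island-scale blocks
  keep the attenuated F2 effect resolvable by a 3 v 3 t-test, which is the
  regime the cross-generation analysis needs to operate in.  The 300 bp
  scale of ordinary planted DMRs exercises the caller itself.

Everything is driven by one ``numpy.random.default_rng`` stream, so a
fixed seed reproduces outputs bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import meth_io

DMR_CLASSES = ("transgenerational", "intergenerational", "F0_only")


@dataclass
class SimConfig:
    seed: int = 0
    n_chroms: int = 2
    # planted DMR classes and geometry
    n_dmrs: dict = field(default_factory=lambda: {
        "transgenerational": 100,
        "intergenerational": 400,
        "F0_only": 1500,
    })
    dmr_length_bp: int = 300            # ordinary planted DMRs
    herit_length_bp: int = 3000         # heritable candidate regions (islands)
    dmr_cpg_spacing_bp: int = 10        # island-like spacing inside regions
    effect: float = 0.3                 # planted |delta beta| in F0
    attenuation: float = 0.8            # per-generation multiplier
    # background
    background_sites_per_chrom: int = 10_000
    bg_cpg_spacing_bp: float = 100.0    # mean geometric spacing
    bg_block_sites: float = 10.0        # mean sites per constant-level domain
    high_weight: float = 0.75           # sperm baseline mass near high level
    # sequencing model
    coverage: float = 20.0
    embryo_coverage: float = 10.0
    dispersion: float = 0.02
    # escape region sets
    n_genes: int = 100
    n_imprinted: int = 20
    n_te: dict = field(default_factory=lambda: {
        "LTR": 100, "LINE": 100, "SINE": 100,
    })
    n_vm_iap: int = 105
    n_vm_iap_variable: int = 18
    te_length_bp: int = 600
    escape_fraction: float = 0.03       # TE regions keeping sperm level at ICM
    # embryo dynamics
    icm_level: float = 0.05
    ps_low_level: float = 0.08
    pgc_level: float = 0.03
    oocyte_level: float = 0.35
    ps_reestablish_prob: float = 0.5    # background sites high at PS
    ps_group_offset: float = 0.3        # stress PS deficit on heritable DMRs
    vm_site_erase_prob: float = 0.85
    vm_site_reestablish_prob: float = 0.80
    vm_reest_below_prob: float = 0.48
    # sncRNA design
    n_seqs: dict = field(default_factory=lambda: {
        "miRNA": 300, "tsRNA": 300, "rsRNA": 500, "piRNA": 200, "other": 100,
    })
    n_planted: dict = field(default_factory=lambda: {
        "tsRNA": ("up", 60), "miRNA": ("down", 100), "rsRNA": ("down", 60),
    })
    fold_change: float = 3.0
    nb_size: float = 25.0
    mean_log_count: float = 4.0
    sd_log_count: float = 1.0
    planted_complementarity: float = 0.9
    embeds_per_dmr: int = 12

    def validate(self) -> None:
        if self.coverage <= 0 or self.embryo_coverage <= 0:
            raise ValueError("coverage must be positive")
        if not (0 <= self.dispersion < 1):
            raise ValueError("dispersion must lie in [0, 1)")
        if not (0 < self.effect <= 1):
            raise ValueError("effect must lie in (0, 1]")
        for name in ("attenuation", "escape_fraction", "ps_reestablish_prob",
                     "vm_site_erase_prob", "vm_site_reestablish_prob",
                     "planted_complementarity"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")


def null_config(seed: int = 0, n_sites: int = 100_000, **overrides) -> SimConfig:
    """A pure-background configuration: no planted regions of any kind.

    Used for calibration runs where the two groups must be exchangeable at
    every CpG.
    """
    cfg = SimConfig(
        seed=seed,
        n_dmrs={},
        n_te={},
        n_vm_iap=0,
        n_vm_iap_variable=0,
        n_genes=0,
        n_imprinted=0,
        background_sites_per_chrom=n_sites // 2,
    )
    return replace(cfg, **overrides)


@dataclass
class SimData:
    """Assembled genome, truth tables and per-site means for one run."""

    config: SimConfig
    sites: pd.DataFrame          # chrom, pos (1-based), sorted
    baseline: np.ndarray         # per-site sperm control mean level
    delta: dict                  # generation -> per-site stress shift
    truth: pd.DataFrame          # planted DMR regions with site spans
    regions: pd.DataFrame        # escape-class regions with site spans
    samples: dict                # sample_id -> count DataFrame (sperm)


def _bimodal(rng, n, high_weight):
    high = rng.beta(15, 2, n)
    low = rng.beta(1, 15, n)
    return np.where(rng.random(n) < high_weight, high, low)


def _betabin(rng, total, mu, phi):
    """Beta-binomial draws; phi ~ 0 degrades gracefully to binomial."""
    mu = np.clip(mu, 1e-4, 1 - 1e-4)
    if phi < 1e-6:
        p = np.broadcast_to(mu, total.shape)
    else:
        s = (1.0 - phi) / phi
        p = rng.beta(mu * s, (1.0 - mu) * s)
    return rng.binomial(total, p)


def _assemble_genome(cfg: SimConfig, rng):
    """Lay out planted regions and background CpGs chromosome by chromosome.

    Returns (sites, baseline, region rows, escape-region rows).  Regions
    are separated by >= ~2 kb of background so that smoothing windows and
    DMR merging never bridge two planted regions.
    """
    planted = []
    for cls in DMR_CLASSES:
        n = cfg.n_dmrs.get(cls, 0)
        length = (cfg.herit_length_bp
                  if cls in ("transgenerational", "intergenerational")
                  else cfg.dmr_length_bp)
        planted += [("dmr", cls, length)] * n
    for te_cls, n in cfg.n_te.items():
        planted += [("region", te_cls, cfg.te_length_bp)] * n
    planted += [("region", "VM_IAP", cfg.te_length_bp)] * cfg.n_vm_iap
    planted += [("region", "imprinted_maternal", cfg.te_length_bp)] * cfg.n_imprinted
    planted += [("region", "gene", 2000)] * cfg.n_genes
    order = rng.permutation(len(planted))
    planted = [planted[i] for i in order]

    chrom_of = np.arange(len(planted)) % cfg.n_chroms
    all_pos, all_chrom, all_base = [], [], []
    dmr_rows, region_rows = [], []
    site_cursor = 0

    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        cursor = 1000
        pos_chunks, base_chunks = [], []

        def add_background(n_sites):
            nonlocal cursor, site_cursor
            if n_sites <= 0:
                return
            gaps = rng.geometric(1.0 / cfg.bg_cpg_spacing_bp, n_sites)
            p = cursor + np.cumsum(gaps)
            # block-constant bimodal domains
            levels = np.empty(n_sites)
            i = 0
            while i < n_sites:
                blk = int(rng.geometric(1.0 / cfg.bg_block_sites))
                levels[i : i + blk] = _bimodal(rng, 1, cfg.high_weight)[0]
                i += blk
            pos_chunks.append(p)
            base_chunks.append(np.clip(levels, 0.01, 0.99))
            cursor = int(p[-1])
            site_cursor += n_sites

        mine = [planted[i] for i in np.flatnonzero(chrom_of == c)]
        for kind, cls, length in mine:
            add_background(int(rng.integers(15, 30)))  # ~2 kb separation
            cursor += int(rng.integers(500, 1000))
            n_sites = max(2, length // cfg.dmr_cpg_spacing_bp)
            p = cursor + np.arange(n_sites) * cfg.dmr_cpg_spacing_bp
            if kind == "dmr":
                base = float(np.clip(_bimodal(rng, 1, cfg.high_weight)[0],
                                     0.05, 0.95))
            else:
                # escape-class regions are highly methylated in sperm
                base = float(np.clip(rng.beta(40, 4), 0.82, 0.99))
            pos_chunks.append(p)
            base_chunks.append(np.full(n_sites, base))
            row = {
                "chrom": chrom,
                "start": int(p[0]) - 1,
                "end": int(p[-1]),
                "cls": cls,
                "baseline": base,
                "si_lo": site_cursor,
                "si_hi": site_cursor + n_sites,
            }
            (dmr_rows if kind == "dmr" else region_rows).append(row)
            cursor = int(p[-1])
            site_cursor += n_sites
        add_background(cfg.background_sites_per_chrom)

        pos = np.concatenate(pos_chunks) if pos_chunks else np.array([], int)
        all_pos.append(pos)
        all_chrom += [chrom] * len(pos)
        all_base.append(np.concatenate(base_chunks) if base_chunks else np.array([]))

    sites = pd.DataFrame({
        "chrom": all_chrom,
        "pos": np.concatenate(all_pos).astype(int),
    })
    baseline = np.concatenate(all_base)
    return sites, baseline, dmr_rows, region_rows


def simulate_methylomes(cfg: SimConfig):
    """Generate the 18 sperm methylomes and the planted-DMR truth table.

    Returns a :class:`SimData`.  ``samples`` maps ids like ``F0_stress_rep2``
    to count tables already in reader form (coverage-filtered at nothing:
    totals of zero are dropped, everything else kept so the caller's own
    >= 5x rule stays in charge).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    sites, baseline, dmr_rows, region_rows = _assemble_genome(cfg, rng)
    n = len(sites)

    truth = pd.DataFrame(dmr_rows)
    regions = pd.DataFrame(region_rows)
    if len(truth):
        truth = truth.reset_index(drop=True)
        truth.insert(0, "region_id", [f"planted_{i:05d}" for i in range(len(truth))])
        sign = np.where(truth["baseline"] > 0.5, -1.0, 1.0)
        truth["direction"] = np.where(sign < 0, "hypo", "hyper")
        for g, gen in enumerate(("F0", "F1", "F2")):
            eff = np.zeros(len(truth))
            live = truth["cls"] == "transgenerational"
            eff[live] = cfg.effect * cfg.attenuation**g
            if g < 2:
                live = truth["cls"] == "intergenerational"
                eff[live] = cfg.effect * cfg.attenuation**g
            if g == 0:
                eff[truth["cls"] == "F0_only"] = cfg.effect
            truth[f"delta_{gen}"] = sign * eff
    if len(regions):
        regions = regions.reset_index(drop=True)
        regions.insert(0, "region_id",
                       [f"{r.cls}_{i:04d}" for i, r in enumerate(regions.itertuples())])
        # which TE regions escape ICM erasure; which VM-IAPs are variable
        esc = np.zeros(len(regions), bool)
        te_like = regions["cls"].isin(list(cfg.n_te) + ["VM_IAP"])
        esc[te_like.to_numpy()] = rng.random(int(te_like.sum())) < cfg.escape_fraction
        regions["escapes_icm"] = esc
        vm = np.flatnonzero((regions["cls"] == "VM_IAP").to_numpy())
        variable = np.zeros(len(regions), bool)
        variable[rng.choice(vm, size=min(cfg.n_vm_iap_variable, len(vm)),
                            replace=False)] = True
        regions["vm_variable"] = variable

    delta = {}
    for gen in ("F0", "F1", "F2"):
        d = np.zeros(n)
        for r in (truth.itertuples() if len(truth) else ()):
            d[r.si_lo : r.si_hi] = getattr(r, f"delta_{gen}")
        delta[gen] = d

    samples = {}
    for gen in ("F0", "F1", "F2"):
        for group in ("control", "stress"):
            mu = np.clip(baseline + (delta[gen] if group == "stress" else 0.0),
                         0.005, 0.995)
            for rep in (1, 2, 3):
                total = rng.poisson(cfg.coverage, n)
                # variable VM-IAPs: per-sample region-level wobble
                mu_s = mu
                if len(regions):
                    mu_s = mu.copy()
                    for r in regions[regions.get("vm_variable", False) == True].itertuples():  # noqa: E712
                        off = rng.normal(0.0, 0.2)
                        mu_s[r.si_lo : r.si_hi] = np.clip(
                            mu_s[r.si_lo : r.si_hi] + off, 0.01, 0.99
                        )
                mC = _betabin(rng, total, mu_s, cfg.dispersion)
                keep = total > 0
                samples[f"{gen}_{group}_rep{rep}"] = pd.DataFrame({
                    "chrom": sites["chrom"][keep].to_numpy(),
                    "pos": sites["pos"][keep].to_numpy(),
                    "mC": mC[keep],
                    "total": total[keep],
                })
    return SimData(cfg, sites, baseline, delta, truth, regions, samples)


def simulate_embryos(sim: SimData):
    """Embryo-stage profiles (ICM/PS/PGC for F1, F2 x groups) plus oocyte.

    Stage means follow the erasure/reestablishment template: ICM low with
    escape regions copying sperm; PS bimodal (about half the sites
    reestablished to the paternal level); PGC lowest.  Heritable planted
    DMRs reestablish at PS with a stress-group deficit
    (``ps_group_offset``); VM-IAP CpGs follow the site-level erase /
    reestablish / below-sperm probabilities.

    Returns ``(samples, emb)`` where ``emb`` maps (gen, group, stage) to
    the per-site mean-level array used (for truth assertions).
    """
    cfg = sim.config
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    n = len(sim.sites)

    # site masks
    heritable = np.zeros(n, bool)
    for r in sim.truth.itertuples() if len(sim.truth) else ():
        if r.cls in ("transgenerational", "intergenerational"):
            heritable[r.si_lo : r.si_hi] = True
    escape = np.zeros(n, bool)
    vm_sites = np.zeros(n, bool)
    for r in sim.regions.itertuples() if len(sim.regions) else ():
        if r.escapes_icm:
            escape[r.si_lo : r.si_hi] = True
        if r.cls == "VM_IAP" and not r.vm_variable:
            vm_sites[r.si_lo : r.si_hi] = True

    # shared stochastic templates (same for both groups, so that group
    # contrasts are null except where an offset is planted)
    ps_high = rng.random(n) < cfg.ps_reestablish_prob
    vm_erase = rng.random(n) < cfg.vm_site_erase_prob
    vm_reest = rng.random(n) < cfg.vm_site_reestablish_prob
    vm_below = rng.random(n) < cfg.vm_reest_below_prob

    samples, emb = {}, {}
    for gen in ("F1", "F2"):
        father = {"F1": "F0", "F2": "F1"}[gen]
        for group in ("control", "stress"):
            sperm_mu = np.clip(
                sim.baseline + (sim.delta[father] if group == "stress" else 0.0),
                0.005, 0.995,
            )
            mu_icm = np.full(n, cfg.icm_level)
            mu_icm[escape] = sperm_mu[escape]
            mu_icm[vm_sites & ~vm_erase] = sperm_mu[vm_sites & ~vm_erase]

            mu_ps = np.where(ps_high, sperm_mu, cfg.ps_low_level)
            mu_ps[heritable] = sperm_mu[heritable]
            if group == "stress":
                mu_ps[heritable] = np.clip(
                    sperm_mu[heritable] - cfg.ps_group_offset, 0.01, 0.99
                )
            reest = vm_sites & vm_erase & vm_reest
            mu_ps[reest] = np.where(
                vm_below[reest],
                np.clip(sperm_mu[reest] - 0.25, 0.02, 0.99),
                sperm_mu[reest],
            )
            mu_ps[vm_sites & vm_erase & ~vm_reest] = cfg.ps_low_level / 2

            mu_pgc = np.full(n, cfg.pgc_level)

            for stage, mu in (("ICM", mu_icm), ("PS", mu_ps), ("PGC", mu_pgc)):
                total = rng.poisson(cfg.embryo_coverage, n)
                mC = _betabin(rng, total, mu, cfg.dispersion)
                keep = total > 0
                samples[f"{gen}_{group}_{stage}"] = pd.DataFrame({
                    "chrom": sim.sites["chrom"][keep].to_numpy(),
                    "pos": sim.sites["pos"][keep].to_numpy(),
                    "mC": mC[keep],
                    "total": total[keep],
                })
                emb[(gen, group, stage)] = mu
    total = rng.poisson(cfg.embryo_coverage, n)
    mC = _betabin(rng, total, np.full(n, cfg.oocyte_level), cfg.dispersion)
    keep = total > 0
    samples["oocyte"] = pd.DataFrame({
        "chrom": sim.sites["chrom"][keep].to_numpy(),
        "pos": sim.sites["pos"][keep].to_numpy(),
        "mC": mC[keep], "total": total[keep],
    })
    return samples, emb


def simulate_reprogramming_arms(
    n_per_arm: int = 300,
    seed: int = 0,
    ps_group_offset: float = 0.3,
    region_reads: int = 300,
    high_weight: float = 0.75,
    icm_level: float = 0.05,
    pgc_level: float = 0.03,
):
    """Region-level erase-and-reestablish simulation for the category
    contrast between heritable and un-heritable DMRs.

    Sperm levels are bimodal; every region is erased at ICM and PGC and
    reestablished at PS, but only heritable regions reestablish with a
    stress-group deficit of ``ps_group_offset``.  Observed levels carry
    counting noise from ``region_reads`` pooled reads.  Returns a
    DataFrame with one row per (arm, region) holding sperm/ICM/PS/PGC
    stress-group levels.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for arm in ("heritable", "unheritable"):
        base = np.clip(_bimodal(rng, n_per_arm, high_weight), 0.1, 0.95)
        offset = ps_group_offset if arm == "heritable" else 0.0
        mu = {
            "sperm": base,
            "ICM": np.full(n_per_arm, icm_level),
            "PS": np.clip(base - offset, 0.02, 0.99),
            "PGC": np.full(n_per_arm, pgc_level),
        }
        obs = {
            k: rng.binomial(region_reads, v) / region_reads
            for k, v in mu.items()
        }
        for i in range(n_per_arm):
            rows.append({
                "arm": arm, "region": f"{arm}_{i}",
                **{k: obs[k][i] for k in mu},
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sncRNA


_SUBCLASS_POOLS = {
    "miRNA": [f"miR-{x}" for x in
              ["let-7", "34c", "21a", "146b", "10b"] + [str(i) for i in range(100, 195)]],
    "tsRNA": ["mt-HisGTG", "GluTTC", "AspGTC", "GlyGCC", "ValCAC",
              "LysCTT", "HisGTG", "SerGCT"] + [f"iso{i:02d}" for i in range(32)],
    "rsRNA": ["18S", "4.5S", "28S", "5.8S"],
    "piRNA": [f"pi-cluster-{i:02d}" for i in range(50)],
    "other": [f"nc-{i:02d}" for i in range(20)],
}

_LENGTH_RANGES = {
    "miRNA": (21, 23), "tsRNA": (28, 34), "rsRNA": (25, 40),
    "piRNA": (26, 31), "other": (18, 40),
}


def simulate_sncrna(cfg: SimConfig, heritable_dmr_ids=None,
                    unheritable_dmr_ids=None, dmr_length_bp: int = 300):
    """Sperm sncRNA count table, DMR FASTA and truth tables.

    Counts are negative-binomial around lognormal baseline means; planted
    differential sequences receive a group fold change with the
    type-specific direction (tsRNAs up, miRNAs and rsRNAs down under
    stress).  When DMR id lists are given, a DMR FASTA is produced in
    which a ``planted_complementarity`` fraction of heritable DMRs carries
    embedded 8-10 bp reverse complements of planted differential
    sequences, and un-heritable DMRs carry none.

    Returns ``(table, dmr_fasta, truth)``; ``dmr_fasta`` is None when no
    DMR ids are supplied.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 7_000_017)
    alphabet = np.array(list("ACGT"))
    rows, truth_rows = [], []
    seen = set()
    for typ, n in cfg.n_seqs.items():
        lo, hi = _LENGTH_RANGES[typ]
        direction, n_plant = cfg.n_planted.get(typ, (None, 0))
        pool = _SUBCLASS_POOLS[typ]
        for i in range(n):
            while True:
                L = int(rng.integers(lo, hi + 1))
                seq = "".join(rng.choice(alphabet, L))
                if seq not in seen:
                    seen.add(seq)
                    break
            planted = direction if i < n_plant else None
            subclass = pool[int(rng.integers(len(pool)))]
            # planted differential sequences sit at high abundance so the
            # fold change is resolvable with three replicates
            lam = float(np.exp(
                rng.normal(cfg.mean_log_count + 1.5, 0.5)
                if planted else rng.normal(cfg.mean_log_count, cfg.sd_log_count)
            ))
            fc = np.ones(6)
            if planted == "up":
                fc[3:] = cfg.fold_change
            elif planted == "down":
                fc[3:] = 1.0 / cfg.fold_change
            mean = lam * fc
            p_nb = cfg.nb_size / (cfg.nb_size + mean)
            counts = rng.negative_binomial(cfg.nb_size, p_nb)
            rows.append({
                "sequence": seq, "subclass": subclass, "type": typ,
                **{c: int(v) for c, v in
                   zip(["c1", "c2", "c3", "s1", "s2", "s3"], counts)},
            })
            truth_rows.append({"sequence": seq, "type": typ,
                               "subclass": subclass, "planted": planted})
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)

    dmr_fasta = None
    if heritable_dmr_ids is not None:
        planted_seqs = truth.loc[truth["planted"].notna(), "sequence"].tolist()
        dmr_fasta = {}
        for ids, carry in ((heritable_dmr_ids, True),
                           (unheritable_dmr_ids or [], False)):
            for did in ids:
                seq = "".join(rng.choice(alphabet, dmr_length_bp))
                if carry and planted_seqs and (
                    rng.random() < cfg.planted_complementarity
                ):
                    for _ in range(cfg.embeds_per_dmr):
                        src = planted_seqs[int(rng.integers(len(planted_seqs)))]
                        k = int(rng.integers(8, 11))
                        start = int(rng.integers(0, len(src) - k + 1))
                        frag = src[start : start + k]
                        from .sncrna import revcomp
                        ins = int(rng.integers(0, dmr_length_bp - k))
                        seq = seq[:ins] + revcomp(frag) + seq[ins + k:]
                dmr_fasta[did] = seq
        return table, dmr_fasta, truth
    return table, dmr_fasta, truth


# ---------------------------------------------------------------------------
# workspace writing (file dialects consumed by the readers)


def write_workspace(sim: SimData, outdir, embryos=None) -> pd.DataFrame:
    """Write coverage files, sample sheet and region BEDs under ``outdir``.

    Returns the sample sheet DataFrame.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    sheet = []
    def emit(sample_id, df, group, gen, stage, rep):
        fname = f"{sample_id}.cov.tsv"
        meth_io.write_counts(df, os.path.join(outdir, fname))
        # paths are relative to the sheet so a workspace is relocatable
        sheet.append({
            "sample_id": sample_id, "group": group, "generation": gen,
            "stage": stage, "replicate": rep, "path": fname,
        })

    for sid, df in sim.samples.items():
        gen, group, rep = sid.split("_")
        emit(sid, df, group, gen, "sperm", int(rep.removeprefix("rep")))
    if embryos:
        for sid, df in embryos.items():
            if sid == "oocyte":
                emit(sid, df, "control", "none", "oocyte", 1)
            else:
                gen, group, stage = sid.split("_")
                emit(sid, df, group, gen, stage, 1)
    sheet = pd.DataFrame(sheet)
    sheet.to_csv(os.path.join(outdir, "samples.tsv"), sep="\t", index=False)
    if len(sim.regions):
        bed = sim.regions.rename(columns={"region_id": "label"})[
            ["chrom", "start", "end", "label", "cls"]
        ]
        meth_io.write_regions(bed, os.path.join(outdir, "regions.bed"))
    if len(sim.truth):
        sim.truth.to_csv(os.path.join(outdir, "planted_truth.tsv"),
                         sep="\t", index=False)
    return sheet
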