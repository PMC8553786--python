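"""Differential methylation calling between two replicated groups.

The site-level model is beta-binomial: replicate j of group g contributes
``mC_j ~ BetaBin(n_j, mu_g, phi_g)`` at each CpG, where ``mu_g`` is the
group methylation level and ``phi_g`` an overdispersion in [0, 1) (phi = 0
recovers the binomial).  Calling proceeds in the classical smoothed-Wald
style:

1. group levels are smoothed with a coverage-weighted moving window
   (default span 500 bp) so that neighbouring CpGs share information;
2. site dispersions are estimated by method of moments across replicates
   and shrunk toward the genome-wide mean with an empirical-Bayes weight,
   stabilising the 3-replicate estimates;
3. a Wald statistic ``(mu_stress - mu_control) / SE`` is formed, with the
   SE derived from the beta-binomial variance of the windowed group means,
   and referred to the standard normal; BH adjustment gives site FDR;
4. significant CpGs (DMCs) are chained into regions (DMRs) and the chains
   filtered on length, CpG count, and a post-hoc effect-size rule.

Group orientation is fixed as stress - control throughout: "hypo" means the
stress group is de-methylated relative to control.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

# published thresholds of the assay design
SMOOTH_SPAN_BP = 500
DMC_EFFECT_MIN = 0.1
DMC_FDR_MAX = 0.01
DMR_MIN_LEN = 50
DMR_MIN_CPG = 4
POSTFILTER_ABS_MIN = 0.1
POSTFILTER_REL_MIN = 0.2
MERGE_GAP_BP = 100

DMR_COLUMNS = [
    "chrom", "start", "end", "dmr_id", "area_stat", "strand",
    "beta_control", "beta_stress", "delta_beta", "direction", "n_cpg",
    "n_dmc", "fdr",
]


def _window_sums(pos: np.ndarray, values: np.ndarray, half_span: float):
    """Sum of ``values`` over sites within +-half_span of each site.

    ``pos`` must be sorted; ``values`` may be 2-D with sites on the last
    axis.  O(n) via cumulative sums.
    """
    lo = np.searchsorted(pos, pos - half_span, side="left")
    hi = np.searchsorted(pos, pos + half_span, side="right")
    c = np.concatenate(
        [np.zeros(values.shape[:-1] + (1,)), np.cumsum(values, axis=-1)], axis=-1
    )
    return c[..., hi] - c[..., lo]


def smooth_levels(
    pos: np.ndarray,
    levels: np.ndarray,
    weights: np.ndarray,
    span_bp: int = SMOOTH_SPAN_BP,
) -> np.ndarray:
    """Coverage-weighted moving-window smoothing of per-site levels.

    The window is centred on each site and spans ``span_bp`` in total
    (+-span_bp/2).  A site with no neighbours in its window returns its raw
    level.  Positions must be sorted and belong to one chromosome.
    """
    pos = np.asarray(pos, dtype=float)
    num = _window_sums(pos, np.asarray(levels, float) * weights, span_bp / 2)
    den = _window_sums(pos, np.asarray(weights, float), span_bp / 2)
    with np.errstate(invalid="ignore"):
        out = num / den
    raw = np.asarray(levels, dtype=float)
    return np.where(den > 0, out, raw)


def estimate_dispersion(
    mC: np.ndarray,
    total: np.ndarray,
    prior_weight: float = 20.0,
    prior: float | None = None,
):
    """Shrunk method-of-moments beta-binomial dispersion per site.

    ``mC``/``total`` are (replicates, sites) arrays for one group.  The raw
    per-site estimate averages, over covered replicates,
    ``((p_j - mu)^2 * m/(m-1) * n_j/(mu(1-mu)) - 1) / (n_j - 1)``
    which is unbiased for phi under the beta-binomial moment structure
    (the m/(m-1) factor corrects for estimating mu from the same data).
    Shrinkage pulls the raw value toward the genome-wide mean ``prior``
    with weight ``prior_weight`` against the site's m-1 within-site
    degrees of freedom; the result is clipped to [0, 0.99).  Sites with a
    single covered replicate, or with mu at the boundary, take the prior.

    Returns ``(phi_shrunk, phi_raw, prior)``.
    """
    mC = np.asarray(mC, float)
    total = np.asarray(total, float)
    covered = total > 0
    m = covered.sum(axis=0)
    N = total.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = mC.sum(axis=0) / N
        p = np.where(covered, mC / np.where(total > 0, total, 1), np.nan)
        v = mu * (1 - mu)
        corr = np.where(m > 1, m / np.maximum(m - 1.0, 1.0), np.nan)
        z = ((p - mu) ** 2 * corr * total / v - 1.0) / np.maximum(total - 1.0, 1.0)
        z = np.where(covered & (total > 1) & np.isfinite(z), z, np.nan)
        n_ok = np.isfinite(z).sum(axis=0)
        phi_raw = np.where(
            n_ok > 0, np.nansum(z, axis=0) / np.maximum(n_ok, 1), np.nan
        )
    degenerate = (m < 2) | (v < 1e-6) | ~np.isfinite(phi_raw)
    phi_raw = np.where(degenerate, np.nan, phi_raw)
    if prior is None:
        finite = phi_raw[np.isfinite(phi_raw)]
        prior = float(np.clip(np.mean(finite), 0.0, 0.99)) if len(finite) else 0.0
    k = np.maximum(m - 1.0, 0.0)
    phi = (k * np.where(np.isfinite(phi_raw), phi_raw, 0.0) + prior_weight * prior) / (
        k * np.isfinite(phi_raw) + prior_weight
    )
    phi = np.where(degenerate, prior, phi)
    return np.clip(phi, 0.0, 0.99), phi_raw, prior


def wald_test_sites(
    index: pd.DataFrame,
    mC_control: np.ndarray,
    total_control: np.ndarray,
    mC_stress: np.ndarray,
    total_stress: np.ndarray,
    span_bp: int = SMOOTH_SPAN_BP,
    prior_weight: float = 20.0,
    smoothing: bool = True,
) -> pd.DataFrame:
    """Site-level smoothed Wald tests, stress vs control.

    ``index`` holds sorted ``chrom, pos`` for the aligned count matrices
    (replicates x sites; total 0 marks a missing site).  Only sites covered
    in at least one replicate of each group are tested.  Returns the
    SiteTest table with smoothed group levels, shrunk dispersions, the Wald
    statistic, two-sided normal p-values and BH-adjusted FDR.
    """
    N1 = total_control.sum(axis=0)
    N2 = total_stress.sum(axis=0)
    keep = (N1 > 0) & (N2 > 0)
    index = index.loc[keep].reset_index(drop=True)
    mC1, tot1 = mC_control[:, keep], total_control[:, keep]
    mC2, tot2 = mC_stress[:, keep], total_stress[:, keep]
    N1, N2 = N1[keep], N2[keep]
    M1, M2 = mC1.sum(axis=0), mC2.sum(axis=0)

    phi1, _, _ = estimate_dispersion(mC1, tot1, prior_weight=prior_weight)
    phi2, _, _ = estimate_dispersion(mC2, tot2, prior_weight=prior_weight)

    # per-site information terms A_g = sum_j n_j (1 + (n_j - 1) phi_g);
    # the variance of a coverage-weighted window mean is
    # mu (1 - mu) * sum A / (sum N)^2 under local constancy of mu.
    A1 = (tot1 * (1.0 + (tot1 - 1.0) * phi1)).sum(axis=0)
    A2 = (tot2 * (1.0 + (tot2 - 1.0) * phi2)).sum(axis=0)

    beta1 = np.empty(len(index))
    beta2 = np.empty(len(index))
    var1 = np.empty(len(index))
    var2 = np.empty(len(index))
    for chrom, sub in index.groupby("chrom", sort=False):
        s = sub.index.to_numpy()
        pos = index["pos"].to_numpy()[s].astype(float)
        half = span_bp / 2 if smoothing else 0.0
        sm_M1 = _window_sums(pos, M1[s].astype(float), half)
        sm_N1 = _window_sums(pos, N1[s].astype(float), half)
        sm_M2 = _window_sums(pos, M2[s].astype(float), half)
        sm_N2 = _window_sums(pos, N2[s].astype(float), half)
        b1 = sm_M1 / sm_N1
        b2 = sm_M2 / sm_N2
        sm_A1 = _window_sums(pos, A1[s].astype(float), half)
        sm_A2 = _window_sums(pos, A2[s].astype(float), half)
        beta1[s], beta2[s] = b1, b2
        var1[s] = b1 * (1 - b1) * sm_A1 / sm_N1**2
        var2[s] = b2 * (1 - b2) * sm_A2 / sm_N2**2

    delta = beta2 - beta1
    # variance floor: a single pooled pseudo-observation, preventing
    # infinite statistics when a group sits exactly at 0 or 1
    p_tilde = (M1 + M2 + 0.5) / (N1 + N2 + 1.0)
    floor = p_tilde * (1 - p_tilde) / (N1 + N2 + 1.0)
    se = np.sqrt(np.maximum(var1 + var2, floor))
    wald = np.where(delta == 0.0, 0.0, delta / se)
    p = 2.0 * stats.norm.sf(np.abs(wald))
    fdr = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])

    out = index.copy()
    out["beta_g1"] = beta1
    out["beta_g2"] = beta2
    out["delta_beta"] = delta
    out["dispersion_g1"] = phi1
    out["dispersion_g2"] = phi2
    out["wald"] = wald
    out["p"] = p
    out["fdr"] = fdr
    return out


def call_dmcs(
    site_tests: pd.DataFrame,
    effect_min: float = DMC_EFFECT_MIN,
    fdr_max: float = DMC_FDR_MAX,
) -> pd.Series:
    """Boolean DMC mask: |delta_beta| > effect_min and fdr < fdr_max."""
    return (site_tests["delta_beta"].abs() > effect_min) & (
        site_tests["fdr"] < fdr_max
    )


def merge_dmcs_to_dmrs(
    site_tests: pd.DataFrame,
    dmc: pd.Series,
    min_len: int = DMR_MIN_LEN,
    min_cpg: int = DMR_MIN_CPG,
    merge_gap_bp: int = MERGE_GAP_BP,
) -> pd.DataFrame:
    """Chain consecutive same-direction DMCs into candidate DMRs.

    Two DMCs join a chain when they are within ``merge_gap_bp``, share the
    sign of delta_beta, and no intervening non-significant CpG reverses the
    sign with |delta| above the DMC effect threshold.  A chain becomes a
    DMR iff it has at least ``min_cpg`` DMCs and spans at least ``min_len``
    bp.  Region group levels are the means of the smoothed levels over all
    tested CpGs in the span (so interleaved non-DMCs dilute the region
    delta, which is what the post-filter exists to catch); candidates whose
    diluted delta no longer agrees in sign with the chain are dropped.
    """
    dmrs = []
    for chrom, sub in site_tests.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        delta = sub["delta_beta"].to_numpy()
        is_dmc = dmc.loc[sub.index].to_numpy()
        idx = np.flatnonzero(is_dmc)
        if len(idx) == 0:
            continue
        chains = [[idx[0]]]
        for a, b in zip(idx[:-1], idx[1:]):
            between = slice(a + 1, b)
            reversal = np.any(
                (np.sign(delta[between]) != np.sign(delta[a]))
                & (np.abs(delta[between]) > DMC_EFFECT_MIN)
            )
            if (
                pos[b] - pos[a] <= merge_gap_bp
                and np.sign(delta[b]) == np.sign(delta[a])
                and not reversal
            ):
                chains[-1].append(b)
            else:
                chains.append([b])
        for chain in chains:
            first, last = chain[0], chain[-1]
            start = int(pos[first]) - 1  # 0-based half-open over the chain
            end = int(pos[last])
            if end - start < min_len or len(chain) < min_cpg:
                continue
            members = slice(first, last + 1)
            b1 = float(sub["beta_g1"].to_numpy()[members].mean())
            b2 = float(sub["beta_g2"].to_numpy()[members].mean())
            d = b2 - b1
            sign = np.sign(delta[first])
            if np.sign(d) != sign:
                continue
            dmrs.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "area_stat": float(sub["wald"].to_numpy()[chain].sum()),
                    "strand": ".",
                    "beta_control": b1,
                    "beta_stress": b2,
                    "delta_beta": d,
                    "direction": "hyper" if sign > 0 else "hypo",
                    "n_cpg": int(last - first + 1),
                    "n_dmc": len(chain),
                    "fdr": float(sub["fdr"].to_numpy()[chain].min()),
                }
            )
    out = pd.DataFrame(dmrs, columns=[c for c in DMR_COLUMNS if c != "dmr_id"])
    out = out.sort_values(["chrom", "start"]).reset_index(drop=True)
    out.insert(3, "dmr_id", [f"dmr_{i:05d}" for i in range(len(out))])
    return out[DMR_COLUMNS]


def postfilter_dmrs(
    dmrs: pd.DataFrame,
    abs_min: float = POSTFILTER_ABS_MIN,
    rel_min: float = POSTFILTER_REL_MIN,
) -> pd.DataFrame:
    """Keep DMRs with |delta| >= abs_min or relative change > rel_min.

    Relative change is |delta| / max(beta_control, 0.01): a region moving
    from (near) unmethylated to methylated counts as a large change even
    when the absolute delta is small.
    """
    d = dmrs["delta_beta"].abs()
    rel = d / np.maximum(dmrs["beta_control"], 0.01)
    return dmrs[(d >= abs_min) | (rel > rel_min)].reset_index(drop=True)


def annotate_dmrs(dmrs: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Assign every region overlapping a DMR by >= 1 bp; else 'intergenic'."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for row in regions.itertuples():
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start, row.end, (row.label, row.cls)
        )
    rows = []
    for row in dmrs.itertuples():
        tree = trees.get(row.chrom)
        hits = tree.overlap(row.start, row.end) if tree is not None else ()
        if not hits:
            rows.append((row.dmr_id, "intergenic", "intergenic"))
        else:
            for hit in sorted(hits):
                rows.append((row.dmr_id, hit.data[0], hit.data[1]))
    return pd.DataFrame(rows, columns=["dmr_id", "label", "cls"])


def call_dmrs(
    index: pd.DataFrame,
    mC_control: np.ndarray,
    total_control: np.ndarray,
    mC_stress: np.ndarray,
    total_stress: np.ndarray,
    span_bp: int = SMOOTH_SPAN_BP,
    effect_min: float = DMC_EFFECT_MIN,
    fdr_max: float = DMC_FDR_MAX,
    min_len: int = DMR_MIN_LEN,
    min_cpg: int = DMR_MIN_CPG,
    merge_gap_bp: int = MERGE_GAP_BP,
    postfilter: bool = True,
):
    """End-to-end site tests -> DMC -> merged, post-filtered DMRs.

    Returns ``(site_tests, dmrs)``.
    """
    tests = wald_test_sites(
        index, mC_control, total_control, mC_stress, total_stress, span_bp=span_bp
    )
    dmc = call_dmcs(tests, effect_min=effect_min, fdr_max=fdr_max)
    dmrs = merge_dmcs_to_dmrs(
        tests, dmc, min_len=min_len, min_cpg=min_cpg, merge_gap_bp=merge_gap_bp
    )
    if postfilter:
        dmrs = postfilter_dmrs(dmrs)
    return tests, dmrs


def write_dmrs(dmrs: pd.DataFrame, path) -> None:
    dmrs.to_csv(path, sep="\t", index=False)


def read_dmrs(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
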