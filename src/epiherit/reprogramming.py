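"""Embryonic reprogramming dynamics of DMRs and escape analysis.

During embryogenesis the paternal methylome is erased toward the inner
cell mass (ICM, E3.5), partially reestablished by the primitive streak
stage (PS, E7.5), and erased again in primordial germ cells (PGC, E13.5).
Each DMR's stage level is compared with the paternal sperm level and
placed in one of five base categories:

* ``free_hypo``  — de-methylated and essentially unmethylated (erased);
* ``other_hypo`` — de-methylated but not fully erased;
* ``full_hyper`` — re-methylated to an essentially full level;
* ``other_hyper``— re-methylated but below full;
* ``unchanged``  — within the delta threshold of the sperm level.

``total_hypo`` and ``total_hyper`` are derived supersets, never counted
independently.  Stress-vs-control stage contrasts yield per-DMR
trajectories over (ICM, PS, PGC) with three states each — 27 patterns.
Escape analysis asks which high-methylated regions (imprinted genes,
transposable-element classes, variably methylated IAPs) retain their
sperm-like level through the erasure waves.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

DELTA_MIN = 0.1
FREE_MAX = 0.1
FULL_MIN = 0.9
HIGH_LEVEL = 0.8
VM_IAP_SD_MAX = 0.1

BASE_CATEGORIES = ("free_hypo", "other_hypo", "full_hyper", "other_hyper",
                   "unchanged")
STAGES = ("ICM", "PS", "PGC")
TRAJ_STATES = ("hypo", "hyper", "unchanged")


def classify_vs_sperm(
    sperm_beta,
    embryo_beta,
    delta_min: float = DELTA_MIN,
    free_max: float = FREE_MAX,
    full_min: float = FULL_MIN,
):
    """Base category of an embryo-stage level relative to paternal sperm.

    Vectorised; inputs may be scalars or arrays.  NaN in either level
    yields the sentinel 'uncovered' (excluded from all denominators).
    """
    s = np.asarray(sperm_beta, float)
    e = np.asarray(embryo_beta, float)
    d = e - s
    cat = np.select(
        [
            (d <= -delta_min) & (e <= free_max),
            d <= -delta_min,
            (d >= delta_min) & (e >= full_min),
            d >= delta_min,
        ],
        ["free_hypo", "other_hypo", "full_hyper", "other_hyper"],
        default="unchanged",
    )
    cat = np.where(np.isfinite(s) & np.isfinite(e), cat, "uncovered")
    return cat if cat.ndim else cat.item()


def category_counts(categories) -> pd.Series:
    """Counts of the five base categories plus derived supersets."""
    c = pd.Series(categories)
    c = c[c != "uncovered"]
    counts = c.value_counts().reindex(BASE_CATEGORIES, fill_value=0)
    counts["total_hypo"] = counts["free_hypo"] + counts["other_hypo"]
    counts["total_hyper"] = counts["full_hyper"] + counts["other_hyper"]
    return counts


def compare_category_distributions(
    heritable_categories,
    unheritable_categories,
) -> pd.DataFrame:
    """Per-category 2x2 Fisher exact contrasts, heritable vs un-heritable.

    For every base category the table is (arm x in-category/not).  The
    un-heritable arm is expected to be an equal-sized sample of the
    non-inherited F0 DMRs.  Degenerate tables (an empty margin) are
    flagged with p = 1 and NaN odds ratio.
    """
    a = pd.Series(heritable_categories)
    b = pd.Series(unheritable_categories)
    a, b = a[a != "uncovered"], b[b != "uncovered"]
    rows = []
    for cat in BASE_CATEGORIES:
        t = np.array(
            [[(a == cat).sum(), (a != cat).sum()],
             [(b == cat).sum(), (b != cat).sum()]]
        )
        degenerate = (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any()
        if degenerate:
            rows.append((cat, *t.ravel(), 1.0, np.nan, True))
        else:
            odds, p = stats.fisher_exact(t, alternative="two-sided")
            rows.append((cat, *t.ravel(), float(p), float(odds), False))
    return pd.DataFrame(
        rows,
        columns=["category", "herit_in", "herit_out", "unherit_in",
                 "unherit_out", "p", "odds_ratio", "degenerate"],
    )


def stage_contrast_significant(fisher_table: pd.DataFrame,
                               alpha: float = 0.01) -> bool:
    """Stage-level call: any category's Holm-adjusted Fisher p < alpha."""
    from statsmodels.stats.multitest import multipletests

    p = fisher_table["p"].to_numpy()
    adj = multipletests(p, method="holm")[1]
    return bool((adj < alpha).any())


def enumerate_trajectories(
    stage_deltas: pd.DataFrame,
    delta_min: float = DELTA_MIN,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-DMR cross-stage trajectory of the stress-vs-control contrast.

    ``stage_deltas`` has columns ICM, PS, PGC of stress - control region
    levels; rows with any NaN receive no trajectory.  Returns the per-DMR
    pattern table and a frequency table over all 27 possible patterns
    (zero-filled), ranked by count.
    """
    def state(d):
        if d <= -delta_min:
            return "hypo"
        if d >= delta_min:
            return "hyper"
        return "unchanged"

    pats = []
    for row in stage_deltas[list(STAGES)].itertuples(index=False):
        if not all(np.isfinite(v) for v in row):
            pats.append(None)
        else:
            pats.append("-".join(state(v) for v in row))
    per_dmr = pd.DataFrame(
        {"pattern": pats}, index=stage_deltas.index
    )
    universe = ["-".join(c) for c in itertools.product(TRAJ_STATES, repeat=3)]
    freq = (
        per_dmr["pattern"].dropna().value_counts()
        .reindex(universe, fill_value=0)
        .rename_axis("pattern")
        .reset_index(name="n")
        .sort_values("n", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    return per_dmr, freq


def escape_profile(
    sperm_levels: np.ndarray,
    embryo_levels: np.ndarray,
    high: float = HIGH_LEVEL,
    delta_min: float = DELTA_MIN,
    free_max: float = FREE_MAX,
) -> dict:
    """Fractions of high-methylated regions escaping erasure at one stage.

    Considers regions with sperm level > ``high`` and a defined embryo
    level.  'maintained' = |embryo - sperm| < delta_min (escape);
    'erased' = embryo level <= free_max; the remainder is 'intermediate'.
    With sperm > 0.8 the first two are mutually exclusive and the three
    fractions sum to one.
    """
    s = np.asarray(sperm_levels, float)
    e = np.asarray(embryo_levels, float)
    mask = np.isfinite(s) & np.isfinite(e) & (s > high)
    s, e = s[mask], e[mask]
    n = len(s)
    if n == 0:
        return {"n": 0, "maintained": np.nan, "erased": np.nan,
                "intermediate": np.nan}
    maintained = np.abs(e - s) < delta_min
    erased = e <= free_max
    inter = ~maintained & ~erased
    return {
        "n": int(n),
        "maintained": float(maintained.mean()),
        "erased": float(erased.mean()),
        "intermediate": float(inter.mean()),
    }


def sample_unheritable(
    dmrs: pd.DataFrame,
    heritable_ids,
    rng,
    match_deciles: bool = True,
) -> list[str]:
    """Seeded equal-sized sample of non-inherited F0 DMRs as the control arm.

    Sampling is without replacement and, by default, matched on the decile
    of |delta_beta| of the heritable set so the two arms have comparable
    effect sizes.  Returns a list of dmr_ids of the same size as
    ``heritable_ids`` (or as many as available).
    """
    heritable_ids = list(heritable_ids)
    pool = dmrs[~dmrs["dmr_id"].isin(heritable_ids)]
    size = min(len(heritable_ids), len(pool))
    if size == 0:
        return []
    if not match_deciles:
        return list(rng.choice(pool["dmr_id"].to_numpy(), size, replace=False))
    h = dmrs[dmrs["dmr_id"].isin(heritable_ids)]
    edges = np.quantile(h["delta_beta"].abs(), np.linspace(0, 1, 11))
    edges[0], edges[-1] = -np.inf, np.inf
    h_bins = np.digitize(h["delta_beta"].abs(), edges[1:-1])
    want = pd.Series(h_bins).value_counts().to_dict()
    p_bins = np.digitize(pool["delta_beta"].abs(), edges[1:-1])
    chosen: list[str] = []
    leftovers = []
    for b, n_want in sorted(want.items()):
        ids = pool["dmr_id"].to_numpy()[p_bins == b]
        ids = rng.permutation(ids)
        chosen += list(ids[:n_want])
        leftovers += list(ids[n_want:])
    short = size - len(chosen)
    if short > 0 and leftovers:
        chosen += list(rng.permutation(np.array(leftovers))[:short])
    return chosen[:size]


def vm_iap_filter(
    region_levels_by_sample: np.ndarray,
    sd_max: float = VM_IAP_SD_MAX,
) -> np.ndarray:
    """Keep mask over VM-IAP regions: sample SD of sperm levels <= sd_max.

    ``region_levels_by_sample`` is (n_regions, n_sperm_samples); the SD is
    the sample (ddof=1) standard deviation over samples with data.
    """
    x = np.asarray(region_levels_by_sample, float)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(x, axis=1, ddof=1)
    return ~(sd > sd_max)


def vm_iap_site_dynamics(
    sperm: np.ndarray,
    icm: np.ndarray,
    ps: np.ndarray,
    delta_min: float = DELTA_MIN,
    free_max: float = FREE_MAX,
) -> dict:
    """Site-level erasure / reestablishment proportions over VM-IAP CpGs.

    Per CpG (arrays of levels; NaN = uncovered, sites must be covered in
    sperm and ICM to enter the denominators):

    * de-methylated in ICM: sperm - ICM >= delta_min;
    * completely erased: de-methylated and ICM level <= free_max;
    * reestablished in PS (among de-methylated sites with PS data):
      PS - ICM >= delta_min;
    * reestablished-below-sperm: reestablished but PS < sperm - delta_min.
    """
    s, i, p = (np.asarray(a, float) for a in (sperm, icm, ps))
    ok = np.isfinite(s) & np.isfinite(i)
    s, i, p = s[ok], i[ok], p[ok]
    n = len(s)
    demeth = (s - i) >= delta_min
    erased = demeth & (i <= free_max)
    with_ps = demeth & np.isfinite(p)
    reest = with_ps & ((p - i) >= delta_min)
    below = reest & (p < s - delta_min)
    def frac(num, den):
        return float(num.sum() / den.sum()) if den.sum() else np.nan
    return {
        "n_sites": int(n),
        "demethylated_icm": frac(demeth, np.ones(n, bool)),
        "erased_of_demethylated": frac(erased, demeth),
        "reestablished_ps": frac(reest, with_ps),
        "reestablished_below_sperm": frac(below, reest),
    }
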