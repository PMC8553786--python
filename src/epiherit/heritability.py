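"""Cross-generation inheritance classification of F0 DMRs.

An F0 sperm DMR is *intergenerationally* inherited when the stress-control
difference is still significant in F1 sperm, and *transgenerationally*
inherited when it is significant in F0, F1 and F2.  Two statistical routes
are provided:

* the per-generation route: a Welch t-test on the three replicate region
  levels of each group within each generation, BH-adjusted across the F0
  DMR universe within that generation;
* the cross-generation route: an exact one-tailed paired Wilcoxon
  signed-rank over the generation-mean (control, stress) pairs, with the
  tail fixed by the F0 direction.

Significance in both routes additionally requires the effect rule
``|delta| >= 0.1 or relative change > 0.2`` (relative change uses the
control level with a 0.01 floor).

A note on the cross-generation route: with n = 3 generation pairs the
exact one-sided signed-rank p-value can never go below 1/8 (1/4 at n = 2),
so a strict 0.01 alpha would label nothing.  The operative default alpha
therefore equals that attainable floor, which turns the test into a
direction-consistency screen across generations; the alpha is a parameter
so stricter (vacuous) settings remain expressible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EFFECT_ABS_MIN = 0.1
EFFECT_REL_MIN = 0.2
GENERATION_FDR_MAX = 0.01
WILCOXON_ALPHA_TRANS = 0.125  # exact floor of the one-sided n=3 signed rank
WILCOXON_ALPHA_INTER = 0.25  # exact floor at n=2

LABELS = ("transgenerational", "intergenerational", "F0_only", "irregular")


def relative_change(delta: np.ndarray, beta_control: np.ndarray) -> np.ndarray:
    """|delta| relative to the control level, denominator floored at 0.01."""
    return np.abs(delta) / np.maximum(np.asarray(beta_control, float), 0.01)


def effect_passes(delta, beta_control,
                  abs_min=EFFECT_ABS_MIN, rel_min=EFFECT_REL_MIN):
    delta = np.asarray(delta, float)
    return (np.abs(delta) >= abs_min) | (
        relative_change(delta, beta_control) > rel_min
    )


def test_generation(
    levels_control: np.ndarray,
    levels_stress: np.ndarray,
) -> dict:
    """Welch t-test on replicate region levels for one DMR, one generation.

    ``levels_*`` are per-replicate region methylation levels (NaN = region
    uncovered in that replicate).  Returns beta_control, beta_stress,
    delta_beta and the two-sided p; ``callable`` is False when fewer than
    two replicates carry data on either side (p is then NaN).
    """
    lc = np.asarray(levels_control, float)
    ls = np.asarray(levels_stress, float)
    lc, ls = lc[np.isfinite(lc)], ls[np.isfinite(ls)]
    out = {
        "beta_control": float(np.mean(lc)) if len(lc) else np.nan,
        "beta_stress": float(np.mean(ls)) if len(ls) else np.nan,
        "callable": len(lc) >= 2 and len(ls) >= 2,
    }
    out["delta_beta"] = out["beta_stress"] - out["beta_control"]
    if not out["callable"]:
        out["p"] = np.nan
        return out
    if np.allclose(lc.var(), 0) and np.allclose(ls.var(), 0):
        out["p"] = 1.0 if np.isclose(out["delta_beta"], 0) else 0.0
        return out
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # near-identical replicate vectors trigger precision warnings;
        # the p-value still degenerates to ~1, which is the right answer
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(ls, lc, equal_var=False)
    out["p"] = float(p) if np.isfinite(p) else 1.0
    return out


def generation_table(
    levels: dict[str, dict[str, np.ndarray]],
    fdr_max: float = GENERATION_FDR_MAX,
) -> pd.DataFrame:
    """Per-generation tests for all DMRs with BH within each generation.

    ``levels[gen][group]`` is an (n_dmrs, n_replicates) array of region
    levels.  Returns a long table with one row per (dmr, generation) and a
    ``significant`` flag applying both the FDR and effect rules.
    """
    frames = []
    for gen, by_group in levels.items():
        lc, ls = by_group["control"], by_group["stress"]
        rows = [test_generation(lc[i], ls[i]) for i in range(lc.shape[0])]
        df = pd.DataFrame(rows)
        df.insert(0, "generation", gen)
        df.insert(0, "dmr_index", np.arange(len(df)))
        p = df["p"].fillna(1.0).to_numpy()
        df["fdr"] = multipletests(p, method="fdr_bh")[1]
        df.loc[~df["callable"], "fdr"] = np.nan
        df["significant"] = (
            df["callable"]
            & (df["fdr"] < fdr_max)
            & effect_passes(df["delta_beta"], df["beta_control"])
        )
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def classify_inheritance(gen_table: pd.DataFrame) -> pd.DataFrame:
    """Per-generation t-test route labels from the significance pattern.

    transgenerational = significant in F0, F1 and F2; intergenerational =
    F0 and F1 but not F2; F0_only = F0 alone; every other pattern (and any
    DMR uncallable in some generation) is irregular.  Direction consistency
    across generations is reported (``direction_consistent``) but not
    required for the label.
    """
    wide = gen_table.pivot(index="dmr_index", columns="generation",
                           values="significant").fillna(False)
    call_ok = gen_table.pivot(index="dmr_index", columns="generation",
                              values="callable").fillna(False)
    deltas = gen_table.pivot(index="dmr_index", columns="generation",
                             values="delta_beta")
    f0 = wide.get("F0", False)
    f1 = wide.get("F1", False)
    f2 = wide.get("F2", False)
    label = np.select(
        [
            f0 & f1 & f2,
            f0 & f1 & ~f2,
            f0 & ~f1 & ~f2,
        ],
        ["transgenerational", "intergenerational", "F0_only"],
        default="irregular",
    )
    label = np.where(call_ok.all(axis=1), label, "irregular")
    signs = np.sign(deltas[["F0", "F1", "F2"]].to_numpy())
    consistent = (signs == signs[:, :1]).all(axis=1)
    return pd.DataFrame(
        {
            "dmr_index": wide.index.to_numpy(),
            "label": label,
            "direction_consistent": consistent,
            "method": "per_generation_ttest",
        }
    )


def _signed_rank_one_sided(diffs: np.ndarray, alternative: str) -> float:
    """Exact one-sided Wilcoxon signed-rank p; zero differences excluded."""
    d = np.asarray(diffs, float)
    d = d[d != 0.0]
    if len(d) == 0:
        return 1.0
    return float(
        stats.wilcoxon(d, alternative=alternative, method="exact").pvalue
    )


def classify_inheritance_wilcoxon(
    gen_means: pd.DataFrame,
    alpha_trans: float = WILCOXON_ALPHA_TRANS,
    alpha_inter: float = WILCOXON_ALPHA_INTER,
) -> pd.DataFrame:
    """Cross-generation signed-rank route.

    ``gen_means`` has one row per DMR with columns ``control_F0,
    stress_F0, ... control_F2, stress_F2`` (generation-mean region levels).
    Generations act as paired replicates: the transgenerational test pairs
    all three generations, the intergenerational test F0 and F1, the tail
    fixed by the sign of the F0 difference.  Significance combines the
    exact p with the per-generation effect rule for every generation in
    scope.  Labels mirror the t-test route.
    """
    rows = []
    for i, r in gen_means.iterrows():
        d = np.array([r[f"stress_{g}"] - r[f"control_{g}"]
                      for g in ("F0", "F1", "F2")])
        bc = np.array([r[f"control_{g}"] for g in ("F0", "F1", "F2")])
        if not np.isfinite(d).all():
            rows.append((i, "irregular", np.nan, np.nan))
            continue
        alt = "greater" if d[0] > 0 else "less"
        p3 = _signed_rank_one_sided(d, alt)
        p2 = _signed_rank_one_sided(d[:2], alt)
        eff = effect_passes(d, bc)
        f0_eff = bool(eff[0])
        if p3 <= alpha_trans and eff.all():
            lab = "transgenerational"
        elif p2 <= alpha_inter and eff[:2].all():
            lab = "intergenerational"
        elif f0_eff:
            lab = "F0_only"
        else:
            lab = "irregular"
        rows.append((i, lab, p3, p2))
    return pd.DataFrame(
        rows, columns=["dmr_index", "label", "p_trans", "p_inter"]
    ).assign(method="cross_generation_wilcoxon")


def inheritance_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per label over all classified DMRs.

    The ``intergenerational`` row is *inclusive* of transgenerational DMRs
    (everything inherited at least one generation), mirroring the usual
    "x% inherited, of which y% transgenerational" phrasing; per-label
    exclusive counts are also reported.
    """
    total = len(calls)
    counts = calls["label"].value_counts()
    rows = []
    n_trans = int(counts.get("transgenerational", 0))
    n_inter_excl = int(counts.get("intergenerational", 0))
    rows.append(("inherited", n_trans + n_inter_excl, total))
    rows.append(("transgenerational", n_trans, total))
    rows.append(("intergenerational_exclusive", n_inter_excl, total))
    rows.append(("F0_only", int(counts.get("F0_only", 0)), total))
    rows.append(("irregular", int(counts.get("irregular", 0)), total))
    return summary_from_counts(rows)


def summary_from_counts(rows) -> pd.DataFrame:
    """Percentage table from (label, n, total) triples, 2-decimal rounding."""
    out = []
    for label, n, total in rows:
        pct = round(100.0 * n / total, 2) if total else 0.0
        out.append({"label": label, "n": n, "total": total, "pct": pct})
    return pd.DataFrame(out)


def delta_trend(abs_deltas: pd.DataFrame) -> dict:
    """Attenuation of |delta_beta| across generations for heritable DMRs.

    ``abs_deltas`` has columns F0, F1, F2 of per-DMR |delta| values.  The
    means per generation are reported with one-sided paired t-tests that
    each next generation's |delta| is smaller.  With fewer than two DMRs
    the tests are skipped (NaN).
    """
    means = {g: float(abs_deltas[g].mean()) for g in abs_deltas.columns}
    ps = {}
    cols = list(abs_deltas.columns)
    for a, b in zip(cols[:-1], cols[1:]):
        if len(abs_deltas) < 2:
            ps[f"{a}->{b}"] = np.nan
            continue
        diff = abs_deltas[a].to_numpy() - abs_deltas[b].to_numpy()
        if np.allclose(diff.std(), 0):
            ps[f"{a}->{b}"] = 1.0 if np.allclose(diff, 0) else np.nan
            continue
        _, p = stats.ttest_rel(abs_deltas[b], abs_deltas[a],
                               alternative="less")
        ps[f"{a}->{b}"] = float(p)
    return {"means": means, "attenuation_p": ps}
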