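"""Sperm small non-coding RNA differential enrichment and DMR matching.

Count tables carry one row per annotated entity (a subclass such as a
miRNA family, tRNA isodecoder or rRNA parent — or a unique sequence) with
six per-sample columns (control x3, stress x3).  Counts are normalised to
reads per million (RPM); entities pass to testing only when the six-sample
totals exceed a floor (sum of counts > 15 and sum of RPM > 1); the test is
a two-sample Student t on RPM at p < 0.05, uncorrected — the screen is
deliberately permissive, mirroring common practice for low-replicate sperm
sncRNA data.  Differential sequences are then matched against DMR
sequences with a 7-bp seed window, directly and as reverse complement
(antisense), extending each seed hit maximally and recording the longest
alignment per (sequence, DMR, mode).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

COUNT_MIN_SUM = 15
RPM_MIN_SUM = 1.0
P_MAX = 0.05
SEED_LEN = 7

SAMPLE_COLUMNS = ["c1", "c2", "c3", "s1", "s2", "s3"]
CONTROL_COLS = ["c1", "c2", "c3"]
STRESS_COLS = ["s1", "s2", "s3"]
TYPES = ("miRNA", "tsRNA", "rsRNA", "piRNA", "other")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_seq(seq: str) -> str:
    """Uppercase and map RNA U to DNA T."""
    return seq.upper().replace("U", "T")


def read_count_table(path) -> pd.DataFrame:
    """TSV: sequence subclass type c1 c2 c3 s1 s2 s3."""
    df = pd.read_csv(path, sep="\t", header=0,
                     dtype={"sequence": str, "subclass": str, "type": str})
    missing = {"sequence", "subclass", "type", *SAMPLE_COLUMNS} - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    df["sequence"] = df["sequence"].map(normalize_seq)
    return df


def rpm_normalize(
    counts: pd.DataFrame,
    library_sizes: np.ndarray | None = None,
) -> pd.DataFrame:
    """RPM per sample: 1e6 * count / library size.

    When ``library_sizes`` is None the table is assumed library-complete
    and column sums are used; RPM columns then sum to exactly 1e6.
    """
    c = counts[SAMPLE_COLUMNS].to_numpy(float)
    lib = np.asarray(
        library_sizes if library_sizes is not None else c.sum(axis=0), float
    )
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    rpm = 1e6 * c / lib
    out = counts.copy()
    for j, col in enumerate(SAMPLE_COLUMNS):
        out[f"rpm_{col}"] = rpm[:, j]
    return out


def _rpm_matrix(table: pd.DataFrame) -> np.ndarray:
    return table[[f"rpm_{c}" for c in SAMPLE_COLUMNS]].to_numpy(float)


def differential_test(
    table: pd.DataFrame,
    count_min: float = COUNT_MIN_SUM,
    rpm_min: float = RPM_MIN_SUM,
    p_max: float = P_MAX,
    variant: str = "student",
) -> pd.DataFrame:
    """Filter and test entities; adds tested/p/differential/direction.

    An entity is tested iff the sum of raw counts over all six samples is
    > ``count_min`` and the sum of RPM > ``rpm_min``.  The test is a
    pooled-variance Student t on RPM by default (``variant='welch'`` for
    unequal variances); direction is the sign of stress - control mean
    RPM.  p-values are raw (no multiple-testing correction), by design.
    """
    rpm = _rpm_matrix(table)
    counts = table[SAMPLE_COLUMNS].to_numpy(float)
    tested = (counts.sum(axis=1) > count_min) & (rpm.sum(axis=1) > rpm_min)
    ctrl, strs = rpm[:, :3], rpm[:, 3:]
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant rows produce a degenerate t; handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(
            strs, ctrl, axis=1, equal_var=(variant == "student")
        )
    # zero variance in both groups: identical means -> p = 1
    degenerate = np.isnan(p)
    p = np.where(degenerate & np.isclose(strs.mean(1), ctrl.mean(1)), 1.0, p)
    p = np.where(np.isnan(p), 1.0, p)
    out = table.copy()
    out["mean_rpm_control"] = ctrl.mean(axis=1)
    out["mean_rpm_stress"] = strs.mean(axis=1)
    out["tested"] = tested
    out["p"] = p
    out["differential"] = tested & (p < p_max)
    out["direction"] = np.where(
        out["mean_rpm_stress"] >= out["mean_rpm_control"], "up", "down"
    )
    return out


def differential_subclasses(table: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Aggregate counts to subclass level, then filter and test."""
    agg = (
        table.groupby(["subclass", "type"], as_index=False)[SAMPLE_COLUMNS]
        .sum()
    )
    agg = rpm_normalize(agg, library_sizes=table[SAMPLE_COLUMNS].sum().to_numpy())
    return differential_test(agg, **kwargs)


def differential_sequences(table: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Filter and test at unique-sequence resolution."""
    if "rpm_c1" not in table.columns:
        table = rpm_normalize(table)
    return differential_test(table, **kwargs)


def composition_report(differential: pd.DataFrame) -> pd.DataFrame:
    """Per-direction composition of the differential set by sncRNA type.

    Counts and 100*n/total (two decimals) per type within each direction;
    an empty direction is flagged with NaN percentages.
    """
    rows = []
    for direction in ("up", "down"):
        sub = differential[
            differential["differential"] & (differential["direction"] == direction)
        ]
        total = len(sub)
        for t in TYPES:
            n = int((sub["type"] == t).sum())
            pct = round(100.0 * n / total, 2) if total else np.nan
            rows.append({"direction": direction, "type": t, "n": n,
                         "total": total, "pct": pct})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# seed-window matching


@dataclass(frozen=True)
class SeedMatch:
    snc_id: str
    dmr_id: str
    mode: str  # "direct" | "antisense"
    longest_match_bp: int


def _longest_extension(query: str, target: str, seed: int) -> int:
    """Longest ungapped exact match of length >= seed between two strings.

    Every seed-length window of ``query`` is located in ``target`` and each
    hit extended maximally in both directions; windows containing N never
    match.  Returns 0 when no window of ``seed`` length matches — this
    equals the longest common substring length whenever that is >= seed.
    """
    nq, nt = len(query), len(target)
    if nq < seed or nt < seed:
        return 0
    # index target seed words
    words: dict[str, list[int]] = {}
    for j in range(nt - seed + 1):
        w = target[j : j + seed]
        if "N" in w:
            continue
        words.setdefault(w, []).append(j)
    best = 0
    for i in range(nq - seed + 1):
        w = query[i : i + seed]
        if "N" in w:
            continue
        for j in words.get(w, ()):
            left = 0
            while (
                i - left - 1 >= 0
                and j - left - 1 >= 0
                and query[i - left - 1] == target[j - left - 1]
                and query[i - left - 1] != "N"
            ):
                left += 1
            right = 0
            while (
                i + seed + right < nq
                and j + seed + right < nt
                and query[i + seed + right] == target[j + seed + right]
                and query[i + seed + right] != "N"
            ):
                right += 1
            best = max(best, left + seed + right)
    return best


def seed_match(
    snc_seq: str,
    dmr_seq: str,
    seed: int = SEED_LEN,
    snc_id: str = "snc",
    dmr_id: str = "dmr",
) -> list[SeedMatch]:
    """Direct and antisense seed-window alignment of a sncRNA to a DMR.

    Direct mode searches the sncRNA itself in the DMR sequence; antisense
    mode searches its reverse complement (base-complementation pairing).
    Per mode the longest maximal extension is recorded; modes without any
    seed-length hit contribute nothing.
    """
    q = normalize_seq(snc_seq)
    t = normalize_seq(dmr_seq)
    out = []
    for mode, query in (("direct", q), ("antisense", revcomp(q))):
        length = _longest_extension(query, t, seed)
        if length >= seed:
            out.append(SeedMatch(snc_id, dmr_id, mode, length))
    return out


def match_all(
    snc_seqs: dict[str, str],
    dmr_seqs: dict[str, str],
    seed: int = SEED_LEN,
) -> pd.DataFrame:
    """All SeedMatches between two sequence collections."""
    rows = []
    for sid, s in snc_seqs.items():
        for did, d in dmr_seqs.items():
            for m in seed_match(s, d, seed=seed, snc_id=sid, dmr_id=did):
                rows.append(
                    (m.snc_id, m.dmr_id, m.mode, m.longest_match_bp)
                )
    return pd.DataFrame(
        rows, columns=["snc_id", "dmr_id", "mode", "longest_match_bp"]
    )


def dmr_alignment_burden(
    matches: pd.DataFrame,
    heritable_ids,
    unheritable_ids,
) -> dict:
    """Counts of distinct aligned differential sequences per DMR.

    Compares the burden distribution of heritable vs un-heritable DMRs
    with a one-sided Mann-Whitney U (heritable greater).  DMRs without a
    single match have burden 0.
    """
    per_dmr = matches.groupby("dmr_id")["snc_id"].nunique()
    burden_h = np.array([int(per_dmr.get(d, 0)) for d in heritable_ids])
    burden_u = np.array([int(per_dmr.get(d, 0)) for d in unheritable_ids])
    if len(burden_h) and len(burden_u) and (
        np.ptp(np.concatenate([burden_h, burden_u])) > 0
    ):
        stat, p = stats.mannwhitneyu(burden_h, burden_u,
                                     alternative="greater")
        stat, p = float(stat), float(p)
    else:
        stat, p = np.nan, 1.0
    return {
        "burden_heritable": burden_h,
        "burden_unheritable": burden_u,
        "mean_heritable": float(burden_h.mean()) if len(burden_h) else np.nan,
        "mean_unheritable": float(burden_u.mean()) if len(burden_u) else np.nan,
        "U": stat,
        "p": p,
    }


def tsrna_targets(
    tsrna_seqs: dict[str, str],
    mrna_seqs: dict[str, str],
    k: int = SEED_LEN,
) -> pd.DataFrame:
    """(tsRNA, mRNA) pairs sharing a perfect antisense k-mer.

    A pair is reported iff some k-mer of the tsRNA's reverse complement
    occurs exactly in the mRNA sequence.
    """
    rows = []
    for mid, mseq in mrna_seqs.items():
        mseq = normalize_seq(mseq)
        kmers = {
            mseq[i : i + k]
            for i in range(len(mseq) - k + 1)
            if "N" not in mseq[i : i + k]
        }
        for tid, tseq in tsrna_seqs.items():
            rc = revcomp(normalize_seq(tseq))
            hit = any(
                rc[i : i + k] in kmers
                for i in range(len(rc) - k + 1)
                if "N" not in rc[i : i + k]
            )
            if hit:
                rows.append((tid, mid))
    return pd.DataFrame(rows, columns=["tsrna_id", "mrna_id"])
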