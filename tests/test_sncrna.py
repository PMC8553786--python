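"""RPM normalisation, differential screening and seed-window matching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from epiherit import sncrna
from epiherit.sncrna import (
    SAMPLE_COLUMNS,
    composition_report,
    differential_sequences,
    differential_subclasses,
    dmr_alignment_burden,
    match_all,
    revcomp,
    rpm_normalize,
    seed_match,
    tsrna_targets,
)


def table_from_counts(rows):
    out = pd.DataFrame(rows, columns=["sequence", "subclass", "type",
                                      *SAMPLE_COLUMNS])
    return out


class TestRpm:
    @pytest.mark.parametrize("count,lib,expected", [
        (100, 1_000_000, 100.0), (0, 1_000_000, 0.0), (5, 2_000_000, 2.5),
    ])
    def test_definition(self, count, lib, expected):
        t = table_from_counts([("ACGTACGTACGTACG", "x", "other",
                                count, 0, 0, 0, 0, 0)])
        out = rpm_normalize(t, library_sizes=np.full(6, lib))
        assert out["rpm_c1"].iloc[0] == pytest.approx(expected)

    def test_library_complete_table_conserves_1e6(self, rng):
        counts = rng.integers(0, 1000, (50, 6))
        t = table_from_counts([
            (f"ACGT{i:011d}".replace("0", "A").replace("1", "C")
             .replace("2", "G")[:15], "x", "other", *row)
            for i, row in enumerate(counts)])
        out = rpm_normalize(t)
        rpm = out[[f"rpm_{c}" for c in SAMPLE_COLUMNS]].to_numpy()
        assert np.allclose(rpm.sum(axis=0), 1e6)

    def test_zero_library_rejected(self):
        t = table_from_counts([("ACGTACGTACGTACG", "x", "other",
                                0, 0, 0, 0, 0, 0)])
        with pytest.raises(ValueError):
            rpm_normalize(t)


class TestDifferential:
    def test_low_count_sum_excluded_before_testing(self):
        t = table_from_counts([
            ("ACGTACGTACGTACG", "a", "miRNA", 2, 2, 2, 1, 2, 1),  # sum 10
            ("TGCATGCATGCATGC", "b", "miRNA", 500, 480, 510, 490, 505, 495),
        ])
        out = differential_sequences(rpm_normalize(
            t, library_sizes=np.full(6, 1e6)))
        assert not out["tested"].iloc[0]
        assert out["tested"].iloc[1]

    def test_clear_fold_change_detected_up(self):
        t = table_from_counts([
            ("ACGTACGTACGTACG", "a", "tsRNA", 10, 11, 12, 30, 31, 29),
            ("TGCATGCATGCATGC", "b", "miRNA", 20, 21, 19, 20, 21, 19),
        ])
        out = differential_sequences(rpm_normalize(
            t, library_sizes=np.full(6, 1e6)))
        row = out.iloc[0]
        assert row["differential"] and row["direction"] == "up"
        # closed form: pooled t on the RPM vectors
        _, p = stats.ttest_ind([30, 31, 29], [10, 11, 12], equal_var=True)
        assert row["p"] == pytest.approx(p)
        assert p < 0.001
        assert not out.iloc[1]["differential"]

    def test_identical_vectors_not_differential(self):
        t = table_from_counts([
            ("ACGTACGTACGTACG", "a", "rsRNA", 50, 50, 50, 50, 50, 50)])
        out = differential_sequences(rpm_normalize(
            t, library_sizes=np.full(6, 1e6)))
        assert out["p"].iloc[0] == 1.0
        assert not out["differential"].iloc[0]

    def test_subclass_aggregation_pools_counts(self):
        t = table_from_counts([
            ("ACGTACGTACGTACG", "fam", "miRNA", 5, 5, 5, 20, 20, 20),
            ("TGCATGCATGCATGC", "fam", "miRNA", 5, 6, 5, 21, 20, 20),
        ])
        out = differential_subclasses(t)
        assert len(out) == 1
        assert out[SAMPLE_COLUMNS].iloc[0].sum() == t[SAMPLE_COLUMNS].sum().sum()


class TestComposition:
    def test_published_style_percentages(self):
        diff = pd.DataFrame({
            "differential": [True] * (61 + 98),
            "direction": ["up"] * 61 + ["down"] * 98,
            "type": ["tsRNA"] * 52 + ["miRNA"] * 5 + ["rsRNA"] * 4
            + ["miRNA"] * 93 + ["rsRNA"] * 5,
        })
        comp = composition_report(diff).set_index(["direction", "type"])
        assert comp.loc[("up", "tsRNA"), "pct"] == 85.25
        assert comp.loc[("down", "miRNA"), "pct"] == 94.90

    def test_empty_direction_flagged(self):
        diff = pd.DataFrame({
            "differential": [True], "direction": ["up"], "type": ["tsRNA"]})
        comp = composition_report(diff).set_index(["direction", "type"])
        assert np.isnan(comp.loc[("down", "miRNA"), "pct"])


def lcs_oracle(a: str, b: str) -> int:
    """Dynamic-programming longest common substring length."""
    dp = np.zeros((len(a) + 1, len(b) + 1), dtype=int)
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                dp[i, j] = dp[i - 1, j - 1] + 1
    return int(dp.max())


class TestSeedMatch:
    def test_direct_example(self):
        out = seed_match("ACGTACGTAC", "TTACGTACGTTT")
        direct = {m.mode: m.longest_match_bp for m in out}
        assert direct["direct"] == 8

    def test_antisense_example(self):
        out = seed_match("AAAACCC", "CCGGGTTTTCC")
        assert [(m.mode, m.longest_match_bp) for m in out] == [
            ("antisense", 7)]

    def test_no_shared_seed_returns_nothing(self):
        assert seed_match("AAAAAAAA", "CCCCCCCCCC") == []

    def test_u_mapped_to_t(self):
        out = seed_match("ACGUACGUAC", "TTACGTACGTTT")
        assert any(m.mode == "direct" and m.longest_match_bp == 8 for m in out)

    def test_ambiguous_bases_never_match(self):
        assert seed_match("ACGNACG" + "TTTTTTT", "ACGNACGTTTTTTT") != []
        # the N-containing 7-mers contribute nothing; the poly-T tail does
        out = seed_match("ACGNACGATCGATC", "GGGACGNACGGGGG")
        assert out == []

    def test_longest_match_equals_lcs_oracle(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(40):
            snc = "".join(rng.choice(bases, 30))
            dmr = "".join(rng.choice(bases, 600))
            # embed a shared fragment half the time to exercise hits
            if rng.random() < 0.5:
                k = int(rng.integers(7, 15))
                i = int(rng.integers(0, 30 - k))
                j = int(rng.integers(0, 600 - k))
                dmr = dmr[:j] + snc[i:i + k] + dmr[j + k:]
            got = {m.mode: m.longest_match_bp
                   for m in seed_match(snc, dmr)}
            want_direct = lcs_oracle(snc, dmr)
            want_anti = lcs_oracle(revcomp(snc), dmr)
            if want_direct >= 7:
                assert got.get("direct") == want_direct
            else:
                assert "direct" not in got
            if want_anti >= 7:
                assert got.get("antisense") == want_anti
            else:
                assert "antisense" not in got

    @given(st.text(alphabet="ACGT", min_size=10, max_size=25),
           st.text(alphabet="ACGT", min_size=20, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_under_double_revcomp(self, snc, dmr):
        a = {(m.mode, m.longest_match_bp) for m in seed_match(snc, dmr)}
        b = {(m.mode, m.longest_match_bp)
             for m in seed_match(revcomp(snc), revcomp(dmr))}
        assert a == b


class TestBurdenAndTargets:
    def test_zero_match_dmr_has_zero_burden(self):
        matches = pd.DataFrame(columns=["snc_id", "dmr_id", "mode",
                                        "longest_match_bp"])
        res = dmr_alignment_burden(matches, ["h1"], ["u1"])
        assert res["mean_heritable"] == 0.0
        assert res["p"] == 1.0

    def test_burden_counts_distinct_sequences(self):
        matches = pd.DataFrame({
            "snc_id": ["s1", "s1", "s2", "s1"],
            "dmr_id": ["h1", "h1", "h1", "u1"],
            "mode": ["direct", "antisense", "direct", "direct"],
            "longest_match_bp": [7, 8, 9, 7],
        })
        res = dmr_alignment_burden(matches, ["h1"], ["u1"])
        assert res["burden_heritable"][0] == 2  # s1 counted once
        assert res["burden_unheritable"][0] == 1

    def test_forced_complement_reported(self):
        pairs = tsrna_targets({"t1": "AAGGGGGGGAA"}, {"m1": "TTCCCCCCCTT"})
        assert pairs.to_dict("records") == [
            {"tsrna_id": "t1", "mrna_id": "m1"}]

    def test_no_shared_antisense_7mer_no_pair(self):
        pairs = tsrna_targets({"t1": "AAAAAAAAAA"}, {"m1": "AAAAAAAAAA"})
        assert len(pairs) == 0

    def test_target_agreement_with_kmer_intersection_oracle(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(50):
            ts = "".join(rng.choice(bases, 30))
            mr = "".join(rng.choice(bases, 200))
            got = len(tsrna_targets({"t": ts}, {"m": mr})) == 1
            rc = revcomp(ts)
            km_ts = {rc[i:i + 7] for i in range(len(rc) - 6)}
            km_mr = {mr[i:i + 7] for i in range(len(mr) - 6)}
            assert got == bool(km_ts & km_mr)
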