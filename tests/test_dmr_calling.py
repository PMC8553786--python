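"""Smoothing, dispersion shrinkage, Wald tests and DMR assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epiherit import dmr_calling, meth_io
from epiherit.dmr_calling import (
    annotate_dmrs,
    call_dmcs,
    estimate_dispersion,
    merge_dmcs_to_dmrs,
    postfilter_dmrs,
    smooth_levels,
    wald_test_sites,
)


class TestSmoothing:
    def test_isolated_site_keeps_raw_level(self):
        out = smooth_levels(np.array([1000]), np.array([0.7]), np.array([10.0]))
        assert out[0] == pytest.approx(0.7)

    def test_two_close_sites_average(self):
        out = smooth_levels(np.array([100, 110]), np.array([0.0, 1.0]),
                            np.array([10.0, 10.0]))
        assert out == pytest.approx([0.5, 0.5])

    def test_window_membership(self):
        # sites at 0/100/600 bp, span 500: the far site sees only itself
        pos = np.array([0, 100, 600])
        out = smooth_levels(pos, np.array([0.9, 0.9, 0.1]),
                            np.ones(3), span_bp=500)
        assert out[2] == pytest.approx(0.1)
        assert out[0] == pytest.approx(0.9)
        assert out[1] == pytest.approx(0.9)

    def test_coverage_weighting(self):
        out = smooth_levels(np.array([100, 120]), np.array([0.0, 1.0]),
                            np.array([30.0, 10.0]))
        assert out[0] == pytest.approx(0.25)


class TestDispersion:
    def test_parameter_recovery_on_simulated_data(self, rng):
        # beta-binomial with phi = 0.1, 10 replicates, 30x, 1000 sites
        phi_true, n_sites, n_rep, cov = 0.1, 1000, 10, 30
        mu = rng.uniform(0.2, 0.8, n_sites)
        s = (1 - phi_true) / phi_true
        total = rng.poisson(cov, (n_rep, n_sites))
        p = rng.beta(mu * s, (1 - mu) * s, (n_rep, n_sites))
        mC = rng.binomial(total, p)
        phi, phi_raw, prior = estimate_dispersion(mC, total)
        assert abs(phi.mean() - phi_true) < 0.2 * phi_true

    def test_no_overdispersion_signal_shrinks_to_near_zero(self):
        # identical proportions in every replicate at high coverage
        total = np.full((4, 50), 100)
        mC = np.full((4, 50), 40)
        phi, _, prior = estimate_dispersion(mC, total)
        assert phi.max() < 0.01

    def test_variable_site_pulled_toward_prior(self, rng):
        total = np.full((3, 2), 50)
        mC = np.array([[25, 2], [25, 48], [25, 25]])
        phi, phi_raw, prior = estimate_dispersion(mC, total)
        wild = phi_raw[1]
        assert (min(wild, prior) < phi[1] < max(wild, prior))


def _aligned_sim(rng, n_sites, delta, cov=30, phi=0.01, spacing=1000):
    """3v3 beta-binomial counts with a uniform group shift."""
    pos = np.arange(n_sites) * spacing + 1
    index = pd.DataFrame({"chrom": "chr1", "pos": pos})
    mu1 = rng.uniform(0.25, 0.7, n_sites)
    mu2 = np.clip(mu1 + delta, 0.01, 0.99)
    def draw(mu):
        s = (1 - phi) / phi
        total = rng.poisson(cov, (3, n_sites))
        p = rng.beta(mu * s, (1 - mu) * s, (3, n_sites))
        return rng.binomial(total, p), total
    m1, t1 = draw(mu1)
    m2, t2 = draw(mu2)
    return index, m1, t1, m2, t2


class TestWaldTest:
    def test_identical_groups_give_null_result(self):
        index = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [100, 2000, 4000]})
        mC = np.array([[5, 0, 10]] * 3)
        tot = np.array([[10, 10, 10]] * 3)
        out = wald_test_sites(index, mC, tot, mC, tot)
        assert np.allclose(out["delta_beta"], 0)
        assert np.allclose(out["p"], 1.0)

    def test_planted_effect_matches_fisher_oracle(self, rng):
        # strong planted shift: tiny p, within an order of magnitude of a
        # Fisher exact test on the pooled counts
        index, m1, t1, m2, t2 = _aligned_sim(rng, 50, 0.5)
        out = wald_test_sites(index, m1, t1, m2, t2, smoothing=False)
        fisher_p = np.array([
            stats.fisher_exact([
                [m1[:, i].sum(), t1[:, i].sum() - m1[:, i].sum()],
                [m2[:, i].sum(), t2[:, i].sum() - m2[:, i].sum()],
            ])[1]
            for i in range(50)
        ])
        assert (out["p"] < 1e-4).all()
        logdiff = np.log10(np.maximum(out["p"], 1e-300)) - np.log10(fisher_p)
        assert np.median(np.abs(logdiff)) < 2.0

    def test_rank_agreement_with_fisher_under_mixed_effects(self, rng):
        index, m1, t1, m2, t2 = _aligned_sim(rng, 300, 0.0)
        # heterogeneous shifts so that p-values spread out
        shift = rng.uniform(-0.3, 0.3, 300)
        mu2 = np.clip(m2.sum(0) / t2.sum(0) + shift, 0.02, 0.98)
        m2 = rng.binomial(t2, mu2)
        out = wald_test_sites(index, m1, t1, m2, t2, smoothing=False)
        fisher_p = np.array([
            stats.fisher_exact([
                [m1[:, i].sum(), t1[:, i].sum() - m1[:, i].sum()],
                [m2[:, i].sum(), t2[:, i].sum() - m2[:, i].sum()],
            ])[1]
            for i in range(300)
        ])
        rho = stats.spearmanr(out["p"], fisher_p).statistic
        assert rho > 0.95


class TestDmcAndMerging:
    @pytest.mark.parametrize("delta,fdr,expect", [
        (0.3, 0.001, True),
        (0.3, 0.05, False),
        (0.08, 1e-9, False),
    ])
    def test_dmc_rule(self, delta, fdr, expect):
        tests = pd.DataFrame({"delta_beta": [delta], "fdr": [fdr]})
        assert call_dmcs(tests).iloc[0] == expect

    def _site_frame(self, pos, delta, dmc):
        n = len(pos)
        return pd.DataFrame({
            "chrom": ["chr1"] * n,
            "pos": pos,
            "beta_g1": np.full(n, 0.6),
            "beta_g2": np.full(n, 0.6) + np.asarray(delta),
            "delta_beta": np.asarray(delta, float),
            "wald": np.sign(delta) * 5.0,
            "fdr": np.where(dmc, 1e-4, 0.5),
        }), pd.Series(dmc)

    def test_chain_of_three_rejected(self):
        tests, dmc = self._site_frame([100, 150, 200], [-0.3] * 3, [True] * 3)
        assert len(merge_dmcs_to_dmrs(tests, dmc)) == 0

    def test_short_span_rejected(self):
        tests, dmc = self._site_frame([100, 110, 120, 130, 140],
                                      [-0.3] * 5, [True] * 5)
        assert len(merge_dmcs_to_dmrs(tests, dmc)) == 0  # 41 bp span

    def test_six_dmc_chain_becomes_one_dmr(self):
        pos = [100, 160, 220, 280, 340, 400]
        tests, dmc = self._site_frame(pos, [-0.3] * 6, [True] * 6)
        dmrs = merge_dmcs_to_dmrs(tests, dmc)
        assert len(dmrs) == 1
        d = dmrs.iloc[0]
        assert (d["start"], d["end"]) == (99, 400)
        assert d["n_dmc"] == 6 and d["n_cpg"] >= 6
        assert d["direction"] == "hypo"
        assert d["end"] - d["start"] == 301

    def test_opposite_sign_intervening_site_breaks_chain(self):
        pos = [100, 160, 220, 250, 280, 340, 400]
        delta = [-0.3, -0.3, -0.3, +0.25, -0.3, -0.3, -0.3]
        dmc = [True, True, True, False, True, True, True]
        tests, dmc = self._site_frame(pos, delta, dmc)
        assert len(merge_dmcs_to_dmrs(tests, dmc)) == 0  # two 3-chains

    def test_gap_breaks_chain(self):
        pos = [100, 160, 220, 280, 500, 560, 620, 680]
        tests, dmc = self._site_frame(pos, [-0.3] * 8, [True] * 8)
        dmrs = merge_dmcs_to_dmrs(tests, dmc)
        assert len(dmrs) == 2  # 220 bp gap > merge_gap_bp


class TestPostfilterAndAnnotation:
    def test_low_absolute_but_large_relative_kept(self):
        dmrs = pd.DataFrame({"delta_beta": [0.07], "beta_control": [0.05]})
        assert len(postfilter_dmrs(dmrs)) == 1

    def test_absolute_criterion_kept(self):
        dmrs = pd.DataFrame({"delta_beta": [0.15], "beta_control": [0.5]})
        assert len(postfilter_dmrs(dmrs)) == 1

    def test_small_change_removed(self):
        dmrs = pd.DataFrame({"delta_beta": [-0.05], "beta_control": [0.80]})
        assert len(postfilter_dmrs(dmrs)) == 0

    def test_annotation_overlap_rules(self):
        dmrs = pd.DataFrame({
            "chrom": ["chr1"] * 3,
            "start": [100, 100, 1000],
            "end": [200, 200, 1100],
            "dmr_id": ["a", "b", "c"],
        }).iloc[[0, 2]]
        regions = pd.DataFrame({
            "chrom": ["chr1", "chr1", "chr1"],
            "start": [199, 200, 990],
            "end": [300, 300, 1200],
            "label": ["one_base", "adjacent", "outer"],
            "cls": ["gene", "gene", "LTR"],
        })
        regions = pd.concat([regions, pd.DataFrame({
            "chrom": ["chr1"], "start": [1040], "end": [1060],
            "label": ["inner"], "cls": ["gene"]})], ignore_index=True)
        ann = annotate_dmrs(dmrs, regions)
        got = ann.groupby("dmr_id")["label"].apply(set).to_dict()
        assert got["a"] == {"one_base"}  # half-open: [200,300) not touched
        assert got["c"] == {"outer", "inner"}  # nested regions both assigned

    def test_no_overlap_is_intergenic(self):
        dmrs = pd.DataFrame({"chrom": ["chr9"], "start": [0], "end": [10],
                             "dmr_id": ["x"]})
        ann = annotate_dmrs(dmrs, pd.DataFrame(
            columns=["chrom", "start", "end", "label", "cls"]))
        assert list(ann["label"]) == ["intergenic"]


class TestCalledDmrInvariants:
    def test_structural_invariants_on_planted_run(self, small_sim):
        from epiherit.experiments import call_f0_dmrs

        tests, dmrs = call_f0_dmrs(small_sim)
        assert len(dmrs) > 0
        assert (dmrs["end"] - dmrs["start"] >= 50).all()
        assert (dmrs["n_dmc"] >= 4).all()
        assert (dmrs["n_cpg"] >= dmrs["n_dmc"]).all()
        hyper = dmrs["direction"] == "hyper"
        assert (np.sign(dmrs["delta_beta"]) == np.where(hyper, 1, -1)).all()
        assert dmrs["delta_beta"].abs().le(1).all()
        assert dmrs["fdr"].between(0, 1).all()
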