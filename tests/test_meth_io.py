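"""Count-table I/O, coverage filtering and region summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from epiherit import meth_io
from epiherit.meth_io import (
    MethylationParseError,
    MethylationValidationError,
    compute_beta,
    read_cytosine_report,
    summarize_region,
)

from conftest import make_counts


def write_lines(tmp_path, lines, name="counts.tsv"):
    p = tmp_path / name
    p.write_text("".join(line + "\n" for line in lines))
    return p


class TestReadCytosineReport:
    def test_coverage_filter_drops_low_sites(self, tmp_path):
        # >=5x rule: a 4x site disappears rather than being zero-filled
        p = write_lines(tmp_path, [
            "chr1\t100\t100\t30.0\t3\t7",
            "chr1\t200\t200\t25.0\t1\t3",
        ])
        df = read_cytosine_report(p, min_coverage=5)
        assert df.to_dict("records") == [
            {"chrom": "chr1", "pos": 100, "mC": 3, "total": 10}
        ]

    def test_empty_file(self, tmp_path):
        df = read_cytosine_report(write_lines(tmp_path, []), min_coverage=5)
        assert len(df) == 0
        assert list(df.columns) == meth_io.COUNT_COLUMNS

    def test_rows_out_of_order_are_sorted(self, tmp_path):
        p = write_lines(tmp_path, [
            "chr2\t50\t50\t0\t5\t5",
            "chr1\t300\t300\t0\t6\t0",
            "chr1\t100\t100\t0\t0\t9",
        ])
        df = read_cytosine_report(p, min_coverage=5)
        assert list(zip(df["chrom"], df["pos"])) == [
            ("chr1", 100), ("chr1", 300), ("chr2", 50)]

    def test_cx_report_strand_collapse(self, tmp_path):
        # +/- strand Cs of one CpG are pooled onto the + strand position
        # before the coverage filter (each strand alone is below 5x)
        p = write_lines(tmp_path, [
            "chr1\t100\t+\t2\t1\tCG\tCGA",
            "chr1\t101\t-\t3\t0\tCG\tCGT",
            "chr1\t500\t+\t1\t1\tCHH\tCTA",
        ])
        df = read_cytosine_report(p, min_coverage=5)
        assert df.to_dict("records") == [
            {"chrom": "chr1", "pos": 100, "mC": 5, "total": 6}
        ]
        separate = read_cytosine_report(p, min_coverage=5,
                                        collapse_strands=False)
        assert len(separate) == 0  # neither strand reaches 5x alone

    def test_malformed_line_names_line_number(self, tmp_path):
        p = write_lines(tmp_path, [
            "chr1\t100\t100\t0\t5\t5",
            "chr1\tnot_a_number\t200\t0\t5\t5",
        ])
        with pytest.raises(MethylationParseError, match="line 2"):
            read_cytosine_report(p)

    def test_roundtrip_is_lossless(self, tmp_path, rng):
        pos = np.sort(rng.choice(100_000, 500, replace=False)) + 1
        total = rng.poisson(20, 500) + 5
        mC = rng.binomial(total, 0.4)
        df = make_counts(list(zip(["chr1"] * 500, pos, mC, total)))
        meth_io.write_counts(df, tmp_path / "rt.tsv")
        back = read_cytosine_report(tmp_path / "rt.tsv", min_coverage=0)
        pd.testing.assert_frame_equal(back, df.astype(back.dtypes))

    @given(min_cov=st.integers(0, 40), raise_by=st.integers(0, 10))
    @settings(max_examples=25, deadline=None)
    def test_coverage_filter_monotone_and_idempotent(self, min_cov, raise_by):
        rng = np.random.default_rng(7)
        total = rng.poisson(15, 200)
        df = make_counts([
            ("chr1", int(p), int(m), int(t))
            for p, t, m in zip(range(10, 2010, 10), total,
                               rng.binomial(total, 0.5))
        ])
        def filt(d, c):
            return d[d["total"] >= c].reset_index(drop=True)
        low = filt(df, min_cov)
        high = filt(df, min_cov + raise_by)
        assert set(map(tuple, high[["chrom", "pos"]].values)) <= set(
            map(tuple, low[["chrom", "pos"]].values))
        pd.testing.assert_frame_equal(filt(low, min_cov), low)


class TestComputeBeta:
    @pytest.mark.parametrize("mC,total,expected", [
        (3, 10, 0.3), (0, 5, 0.0), (21, 21, 1.0),
    ])
    def test_levels(self, mC, total, expected):
        assert compute_beta(mC, total) == pytest.approx(expected)

    def test_zero_total_is_an_error(self):
        with pytest.raises(MethylationValidationError):
            compute_beta(0, 0)

    def test_mc_exceeding_total_is_an_error(self):
        with pytest.raises(MethylationValidationError):
            compute_beta(7, 5)


class TestSummarizeRegion:
    def test_mean_of_site_levels(self):
        df = make_counts([("chr1", 10, 2, 10), ("chr1", 20, 8, 10)])
        s = summarize_region(df, "chr1", 0, 100)
        assert s["mean_level"] == pytest.approx(0.5)
        assert s["n_covered"] == 2

    def test_empty_region_flags_missing(self):
        df = make_counts([("chr1", 10, 2, 10)])
        s = summarize_region(df, "chr1", 500, 600)
        assert s["n_covered"] == 0
        assert np.isnan(s["mean_level"]) and np.isnan(s["pooled_level"])

    def test_pooled_level_weights_by_coverage(self):
        df = make_counts([("chr1", 10, 1, 10), ("chr1", 20, 9, 10)])
        s = summarize_region(df, "chr1", 0, 100)
        assert s["pooled_level"] == pytest.approx(0.5)

    def test_pooled_counts_additive_over_disjoint_subregions(self, rng):
        pos = np.arange(1, 301)
        total = rng.poisson(10, 300) + 1
        df = make_counts(list(zip(["chr1"] * 300, pos,
                                  rng.binomial(total, 0.3), total)))
        whole = summarize_region(df, "chr1", 0, 300)
        a = summarize_region(df, "chr1", 0, 123)
        b = summarize_region(df, "chr1", 123, 300)
        pooled_mC = (a["pooled_level"] * 0 + 0)  # noqa - recompute below
        # reconstruct pooled counts: level * total reads in part
        reads_a = df[df["pos"] - 1 < 123]["total"].sum()
        reads_b = df[df["pos"] - 1 >= 123]["total"].sum()
        combined = (a["pooled_level"] * reads_a + b["pooled_level"] * reads_b) / (
            reads_a + reads_b)
        assert combined == pytest.approx(whole["pooled_level"])
        assert a["n_covered"] + b["n_covered"] == whole["n_covered"]

    def test_region_levels_matches_scalar_summary(self, rng):
        pos = np.sort(rng.choice(5000, 200, replace=False)) + 1
        total = rng.poisson(10, 200) + 1
        df = make_counts(list(zip(["chr1"] * 200, pos,
                                  rng.binomial(total, 0.6), total)))
        regions = pd.DataFrame({
            "chrom": ["chr1"] * 3, "start": [0, 1000, 4900],
            "end": [1000, 2000, 4999]})
        vec, ncov = meth_io.region_levels(df, regions, kind="pooled")
        for i, r in regions.iterrows():
            s = summarize_region(df, r["chrom"], r["start"], r["end"])
            if s["n_covered"]:
                assert vec[i] == pytest.approx(s["pooled_level"])
            else:
                assert np.isnan(vec[i])
            assert ncov[i] == s["n_covered"]


class TestSampleSheetAndRegions:
    def test_sample_sheet_roundtrip_and_validation(self, tmp_path):
        rows = [
            "sample_id\tgroup\tgeneration\tstage\treplicate\tpath",
            "F0_control_rep1\tcontrol\tF0\tsperm\t1\tx.tsv",
            "F0_stress_rep1\tstress\tF0\tsperm\t1\tx.tsv",
        ]
        p = tmp_path / "s.tsv"
        p.write_text("\n".join(rows) + "\n")
        sheet = meth_io.read_sample_sheet(p)
        assert len(sheet) == 2
        rows.append("dup\tstress\tF0\tsperm\t1\ty.tsv")
        p.write_text("\n".join(rows) + "\n")
        with pytest.raises(MethylationValidationError, match="not unique"):
            meth_io.read_sample_sheet(p)

    def test_sperm_requires_generation(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(
            "sample_id\tgroup\tgeneration\tstage\treplicate\tpath\n"
            "x\tcontrol\tnone\tsperm\t1\tx.tsv\n")
        with pytest.raises(MethylationValidationError, match="generation"):
            meth_io.read_sample_sheet(p)

    def test_regions_roundtrip_and_merge(self, tmp_path):
        df = pd.DataFrame({
            "chrom": ["chr1", "chr1", "chr1"],
            "start": [100, 150, 400],
            "end": [200, 300, 500],
            "label": ["a", "b", "c"],
            "cls": ["LTR", "LTR", "LINE"],
        })
        meth_io.write_regions(df, tmp_path / "r.bed")
        back = meth_io.read_regions(tmp_path / "r.bed", name="r")
        assert list(back["cls"]) == ["LTR", "LTR", "LINE"]
        merged = meth_io.merge_same_class(back)
        ltr = merged[merged["cls"] == "LTR"]
        assert len(ltr) == 1
        assert (ltr["start"].iloc[0], ltr["end"].iloc[0]) == (100, 300)
        # merged same-class regions are non-overlapping
        for _, grp in merged.groupby(["chrom", "cls"]):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            assert (starts[1:] >= ends[:-1]).all()

    def test_fasta_roundtrip(self, tmp_path):
        seqs = {"dmr_1": "ACGT" * 30, "dmr_2": "TTTTAAAA"}
        meth_io.write_fasta(seqs, tmp_path / "x.fasta")
        assert meth_io.read_fasta(tmp_path / "x.fasta") == seqs
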