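"""Context classification, window binning, and the filtering rules."""

import numpy as np
import pandas as pd
import pytest

from epiqtl.datatypes import BIN_META_COLUMNS, GenotypeMatrix
from epiqtl.preprocess import (
    anscombe,
    bin_methylation_levels,
    classify_cytosine_context,
    filter_expression,
    filter_methylation_bins,
    filter_snps_maf,
    five_furthest_score,
    inverse_normal_transform,
)


class TestContextClassification:
    @pytest.mark.parametrize(
        "triplet,expected",
        [("CGA", "CG"), ("CGG", "CG"), ("CAG", "CHG"), ("CTG", "CHG"),
         ("CTT", "CHH"), ("CAA", "CHH"), ("CCC", "CHH")],
    )
    def test_definition(self, triplet, expected):
        assert classify_cytosine_context(triplet) == expected

    @pytest.mark.parametrize("bad", ["AGA", "GCG", "CG", "CGAA"])
    def test_rejects_non_cytosine_triplets(self, bad):
        with pytest.raises(ValueError):
            classify_cytosine_context(bad)


def _records(rows):
    return pd.DataFrame(
        rows, columns=["accession", "chrom", "pos", "strand", "context",
                       "mc_count", "total_count"]
    )


class TestBinning:
    def test_single_site_mean(self):
        rec = _records([("a1", "1", 250, "+", "CGA", 5, 10)])
        bins = bin_methylation_levels(rec, window=200, step=100)
        assert len(bins) == 2  # site covered by windows starting at 100 and 200
        assert (bins["context_class"] == "CG_only").all()
        assert np.allclose(bins["a1"], 0.5)

    def test_chg_presence_relabels_cg_bin(self):
        rec = _records([
            ("a1", "1", 250, "+", "CGA", 5, 10),
            ("a1", "1", 260, "+", "CAG", 1, 10),  # methylated CHG, same window
        ])
        bins = bin_methylation_levels(rec, window=200, step=200)
        cg = bins[bins["context_class"].str.startswith("CG")]
        assert set(cg["context_class"]) == {"CG_in_C"}
        # an unmethylated CHG site does not trigger the TE-like label
        rec0 = _records([
            ("a1", "1", 250, "+", "CGA", 5, 10),
            ("a1", "1", 260, "+", "CAG", 0, 10),
        ])
        bins0 = bin_methylation_levels(rec0, window=200, step=200)
        cg0 = bins0[bins0["context_class"].str.startswith("CG")]
        assert set(cg0["context_class"]) == {"CG_only"}

    def test_window_membership_matches_brute_force(self):
        rng = np.random.default_rng(0)
        rows = []
        for acc in ("a1", "a2"):
            for pos in rng.integers(1, 2000, size=80):
                rows.append((acc, "1", int(pos), "+", "CTT",
                             int(rng.integers(0, 5)), 10))
        rec = _records(rows)
        window, step = 200, 100
        bins = bin_methylation_levels(rec, window=window, step=step)
        # brute force: every (start, accession) mean over covered sites
        for _, b in bins.iterrows():
            for acc in ("a1", "a2"):
                sub = rec[(rec["accession"] == acc)
                          & (rec["pos"] - 1 >= b["start"])
                          & (rec["pos"] - 1 < b["start"] + window)]
                assert np.isclose(b[acc], (sub["mc_count"] / sub["total_count"]).mean())
        # a site at 1-based position 251 (0-based 250) joins exactly the
        # windows starting at 100 and 200
        starts = bins[(bins["context_class"] == "CHH")]["start"]
        one = bin_methylation_levels(
            _records([("a1", "1", 251, "+", "CTT", 1, 2)]), window=200, step=100
        )
        assert sorted(one["start"]) == [100, 200]

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        rows = [("a1", "1", int(p), "+", "CGA", int(rng.integers(0, 9)), 10)
                for p in rng.integers(1, 1000, size=50)]
        rec = _records(rows)
        shuffled = rec.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = bin_methylation_levels(rec)
        b = bin_methylation_levels(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_coverage_sites_are_ineligible(self):
        rec = _records([
            ("a1", "1", 50, "+", "CGA", 0, 0),
            ("a1", "1", 60, "+", "CGA", 8, 10),
        ])
        bins = bin_methylation_levels(rec, window=200, step=200)
        assert np.allclose(bins["a1"], 0.8)


class TestSnpFilter:
    def _geno(self, carriers, n=135):
        col = np.zeros((n, 1), dtype=np.int8)
        col[:carriers, 0] = 1
        return GenotypeMatrix(matrix=col, chrom=["1"], pos=[0],
                              accessions=[f"a{i}" for i in range(n)])

    def test_maf_boundary_at_6_vs_7_of_135(self):
        assert filter_snps_maf(self._geno(6)).n_snps == 0   # 6/135 = 0.0444
        assert filter_snps_maf(self._geno(7)).n_snps == 1   # 7/135 = 0.0519

    def test_monomorphic_removed(self):
        assert filter_snps_maf(self._geno(0)).n_snps == 0
        assert filter_snps_maf(self._geno(135)).n_snps == 0


class TestExpressionFilter:
    def test_silent_gene_removed_by_anscombe_mean(self):
        expr = pd.DataFrame([[0.0] * 10], index=["g"])
        assert float(anscombe(0)) == pytest.approx(2 * np.sqrt(0.375))
        assert len(filter_expression(expr)) == 0

    def test_constant_gene_removed_by_cv(self):
        expr = pd.DataFrame([[50.0] * 10], index=["g"])
        assert len(filter_expression(expr)) == 0

    def test_alternating_gene_kept(self):
        expr = pd.DataFrame([[10.0, 12.0] * 6], index=["g"])
        assert len(filter_expression(expr)) == 1

    def test_negative_rpkm_rejected(self):
        with pytest.raises(ValueError):
            filter_expression(pd.DataFrame([[-1.0, 2.0]], index=["g"]))


def _bin_frame(levels):
    levels = np.atleast_2d(levels)
    df = pd.DataFrame(
        {"chrom": "1", "start": 0, "end": 200, "context_class": "CG_only"},
        index=range(len(levels)),
    )
    for j in range(levels.shape[1]):
        df[f"a{j}"] = levels[:, j]
    return df


class TestMethylationBinFilter:
    def test_near_binary_rare_bin_removed(self):
        levels = np.zeros(135)
        levels[0] = 1.0
        assert five_furthest_score(levels) > 75
        assert five_furthest_score(levels) == pytest.approx(134.0, rel=0.01)
        assert len(filter_methylation_bins(_bin_frame(levels))) == 0

    def test_gaussian_bins_mostly_kept(self):
        rng = np.random.default_rng(0)
        # standard-normal vectors score ~20-35; use positive-mean shift so the
        # CV rule does not interfere
        scores = [five_furthest_score(rng.normal(size=135)) for _ in range(300)]
        assert np.mean(np.asarray(scores) <= 75) >= 0.99

    def test_constant_bin_removed_by_cv(self):
        assert len(filter_methylation_bins(_bin_frame(np.full(135, 0.5)))) == 0

    def test_filter_is_idempotent(self):
        rng = np.random.default_rng(2)
        frame = _bin_frame(0.5 + 0.2 * rng.standard_normal((40, 135)))
        once = filter_methylation_bins(frame)
        twice = filter_methylation_bins(once)
        pd.testing.assert_frame_equal(once, twice)
        assert len(once) <= len(frame)


class TestInverseNormal:
    def test_three_point_quantiles_with_zero_offset(self):
        out = inverse_normal_transform(np.array([5.0, 1.0, 3.0]), c=0.0)
        np.testing.assert_allclose(sorted(out), [-0.6744898, 0.0, 0.6744898],
                                   atol=1e-6)

    def test_rank_preserving(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(3)
        x = rng.gamma(2.0, size=50)
        out = inverse_normal_transform(x)
        assert spearmanr(x, out).statistic == pytest.approx(1.0)

    def test_symmetric_ranks_sum_to_zero(self):
        out = inverse_normal_transform(np.array([10.0, 20.0, 30.0, 40.0]))
        assert abs(out.sum()) < 1e-12

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError):
            inverse_normal_transform(np.ones(10))
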