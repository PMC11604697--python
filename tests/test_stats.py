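"""Rank-sum, state enrichment, gene-set overlap, DDCt and paired t."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from capv2g.intervals import IntervalSet
from capv2g.stats import (
    chromhmm_enrichment,
    expression_contact_comparison,
    format_pvalue,
    geneset_overlap_test,
    paired_t_test,
    qpcr_ddct,
    rank_sum_test,
)


class TestRankSum:
    def test_extreme_small_sample(self):
        # all 6 rank assignments enumerable by hand: P(U <= 0) = 1/6
        res = rank_sum_test([1, 2], [3, 4])
        assert res.u == 0
        assert res.p_two_sided == pytest.approx(2 / 6)
        assert res.method == "exact"

    def test_identical_multisets_give_p_one(self):
        res = rank_sum_test([1, 2, 2, 3], [1, 2, 2, 3])
        assert res.p_two_sided == pytest.approx(1.0, abs=1e-9)

    def test_exact_agrees_with_scipy_exact(self):
        rng = np.random.default_rng(3)
        for n1 in range(1, 6):
            for n2 in range(1, 6):
                if n1 + n2 > 10:
                    continue
                x = rng.normal(size=n1)
                y = rng.normal(size=n2)
                ours = rank_sum_test(x, y)
                ref = sps.mannwhitneyu(x, y, method="exact",
                                       alternative="two-sided")
                assert ours.method == "exact"
                assert ours.u == pytest.approx(ref.statistic)
                assert ours.p_two_sided == pytest.approx(ref.pvalue)

    def test_exact_and_normal_paths_agree_at_n10_each(self):
        rng = np.random.default_rng(7)
        from capv2g import stats as cstats

        for _ in range(50):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            exact = cstats._exact_rank_sum(np.sort(x), np.sort(y))
            approx = cstats._normal_rank_sum(x, y)
            assert abs(exact.p_two_sided - approx.p_two_sided) <= 0.02

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(12)
        x = rng.normal(2.0, 1.0, size=60)
        y = rng.normal(0.0, 1.0, size=60)
        res = rank_sum_test(x, y)
        assert res.p_two_sided < 0.05
        assert res.p_greater < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    def test_pvalue_floor_formatting(self):
        assert format_pvalue(1e-20) == "< 2.2e-16"
        assert format_pvalue(0.0243) == "0.0243"


class TestExpressionComparison:
    def make_expr(self, values):
        return pd.Series(values, index=[f"G{i}" for i in range(len(values))])

    def test_connected_genes_higher(self):
        expr = self.make_expr([7.0, 7.0, 7.0, 0.0, 0.0, 0.0])
        res = expression_contact_comparison(expr, ["G0", "G1", "G2"])
        assert res.direction == "greater"
        assert res.p_two_sided < 0.05

    def test_unknown_connected_genes_skipped(self):
        expr = self.make_expr([5.0, 5.0, 1.0, 1.0])
        res = expression_contact_comparison(expr, ["G0", "G1", "GX"])
        assert res.n1 == 2

    def test_empty_connected_set_rejected(self):
        expr = self.make_expr([1.0, 2.0])
        with pytest.raises(ValueError):
            expression_contact_comparison(expr, ["GX"])


class TestChromHMMEnrichment:
    def seg(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])

    def test_query_inside_small_state(self):
        # 1000 bp query wholly inside a state covering 5% of a 1 Mb genome
        seg = self.seg([("chr1", 0, 50_000, "enh"),
                        ("chr1", 50_000, 1_000_000, "quies")])
        query = IntervalSet.from_tuples([("chr1", 10_000, 11_000)])
        (enh, quies) = chromhmm_enrichment(query, seg, 1_000_000)
        assert enh.fold == pytest.approx(20.0)
        assert enh.log2_fold == pytest.approx(math.log2(20.0))
        assert quies.log2_fold == float("-inf")

    def test_half_overlap(self):
        seg = self.seg([("chr1", 0, 50_000, "enh"),
                        ("chr1", 50_000, 1_000_000, "quies")])
        query = IntervalSet.from_tuples([("chr1", 49_500, 50_500)])
        enh = chromhmm_enrichment(query, seg, 1_000_000)[0]
        assert enh.fold == pytest.approx(10.0)
        assert enh.log2_fold == pytest.approx(math.log2(10.0))

    def test_proportional_query_gives_zero_log2(self):
        seg = self.seg([("chr1", 0, 200_000, "a"),
                        ("chr1", 200_000, 1_000_000, "b")])
        # query covers 1% of every state
        query = IntervalSet.from_tuples(
            [("chr1", 0, 2000), ("chr1", 200_000, 208_000)]
        )
        for res in chromhmm_enrichment(query, seg, 1_000_000):
            assert res.log2_fold == pytest.approx(0.0)

    def test_empty_query_rejected(self):
        seg = self.seg([("chr1", 0, 1000, "a")])
        with pytest.raises(ValueError):
            chromhmm_enrichment(IntervalSet(), seg, 1000)

    def test_fold_conservation_over_covered_genome(self):
        rng = np.random.default_rng(9)
        segments, pos = [], 0
        states = ["a", "b", "c", "d"]
        while pos < 100_000:
            ln = int(rng.integers(500, 3000))
            segments.append(
                ("chr1", pos, min(pos + ln, 100_000),
                 states[int(rng.integers(4))])
            )
            pos += ln
        seg = self.seg(segments)
        query = IntervalSet.from_tuples(
            [("chr1", int(s), int(s) + 200)
             for s in rng.integers(0, 99_800, size=40)]
        )
        covered = sum(e - s for _, s, e, _ in segments)
        results = chromhmm_enrichment(query, seg, covered)
        weighted = sum(r.fold * r.state_bp / covered for r in results)
        assert weighted == pytest.approx(1.0)


class TestGenesetOverlap:
    def test_exact_hypergeometric_sum(self):
        universe = [f"g{i}" for i in range(20)]
        hits = universe[:5]
        reference = universe[2:6]
        res = geneset_overlap_test(hits, reference, universe)
        assert res.overlap == 3
        expected = sum(
            sps.hypergeom.pmf(k, 20, 4, 5) for k in (3, 4)
        )
        assert res.p_one_sided == pytest.approx(expected)
        assert res.table.sum() == 20

    def test_hits_equal_universe(self):
        universe = [f"g{i}" for i in range(10)]
        res = geneset_overlap_test(universe, universe[:4], universe)
        assert res.overlap == 4
        assert res.p_one_sided == pytest.approx(1.0)

    def test_zero_overlap_p_near_one(self):
        universe = [f"g{i}" for i in range(30)]
        res = geneset_overlap_test(universe[:3], universe[25:], universe)
        assert res.overlap == 0
        assert res.p_one_sided > 0.5

    def test_non_subset_rejected(self):
        with pytest.raises(ValueError):
            geneset_overlap_test(["x"], ["a"], ["a", "b"])


class TestQpcrDDCt:
    def make(self, rows):
        return pd.DataFrame(rows, columns=["sample", "target_ct", "control_ct"])

    def test_worked_example(self):
        ct = self.make([("treated", 20.0, 18.0), ("control", 19.0, 18.0)])
        out = qpcr_ddct(ct, "control")
        rel = dict(zip(out["sample"], out["relative_expression"]))
        assert rel["treated"] == pytest.approx(0.5)
        assert rel["control"] == pytest.approx(1.0)

    def test_equal_delta_ct_everywhere(self):
        ct = self.make([("a", 21.0, 18.0), ("b", 24.0, 21.0), ("c", 19.0, 16.0)])
        out = qpcr_ddct(ct, "a")
        assert np.allclose(out["relative_expression"], 1.0)

    def test_missing_control_ct_rejected(self):
        ct = self.make([("a", 21.0, np.nan)])
        with pytest.raises(ValueError):
            qpcr_ddct(ct, "a")


class TestPairedT:
    def test_identical_samples(self):
        res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p_two_sided == 1.0 and res.degenerate

    def test_constant_difference_flagged_degenerate(self):
        res = paired_t_test([1, 2, 3, 4], [2, 3, 4, 5])
        assert res.degenerate and res.p_two_sided == 0.0

    def test_hand_computed_example(self):
        # differences {2, 2, 1, 2}: mean 1.75, sd 0.5, t = 1.75/(0.5/2) = 7
        res = paired_t_test([10, 12, 11, 13], [12, 14, 12, 15])
        assert res.t == pytest.approx(7.0)
        assert res.df == 3
        assert res.p_two_sided == pytest.approx(2 * sps.t.sf(7.0, 3))
        assert res.percent_change == pytest.approx(
            100 * (13.25 - 11.5) / 11.5
        )

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1, 2], [1, 2, 3])
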