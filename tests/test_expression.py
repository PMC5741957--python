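"""Differential-expression statistics and the cross-method consensus."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.special import comb

from droughtgenes import (
    bh_fdr,
    consensus,
    de_analysis,
    fisher_counts,
    fold_change_call,
    rank_product,
    ttest_unpaired,
)
from droughtgenes.synthetic import gen_expression
from tests.conftest import make_matrix


class TestFoldChange:
    def test_four_fold_up(self):
        m = make_matrix([[8, 8, 8, 2, 2, 2]])
        out = fold_change_call(m, "treatment")
        # integer counts use a pseudocount of 1: (8+1)/(2+1) = 3
        assert out["log2_fold_change"].iloc[0] == pytest.approx(np.log2(3))
        assert out["direction"].iloc[0] == "up"

    def test_identical_groups_are_none(self):
        m = make_matrix([[5, 5, 5, 5, 5, 5]])
        out = fold_change_call(m, "treatment")
        assert out["log2_fold_change"].iloc[0] == 0.0
        assert out["direction"].iloc[0] == "none"

    def test_abundance_scale_uses_small_pseudocount(self):
        m = make_matrix([[8.5, 8.5, 8.5, 2.125, 2.125, 2.125]])
        out = fold_change_call(m, "treatment")
        assert out["log2_fold_change"].iloc[0] == pytest.approx(2.0, abs=0.01)
        assert out["direction"].iloc[0] == "up"

    def test_planted_fold_changes_called_up(self):
        m, truth = gen_expression(
            n_genes=300, de_fraction=0.05, log2fc=np.log2(2.5), sigma=0.1, seed=61
        )
        out = fold_change_call(m, "treatment")
        for gid in truth.de_genes:
            assert out.loc[gid, "direction"] == "up"


class TestTtest:
    def test_frozen_pooled_t_example(self):
        # pooled t for {1,2,3} vs {4,5,6}: t = -3.674, df = 4, p = 0.0213
        m = make_matrix([[1, 2, 3, 4, 5, 6]])
        out = ttest_unpaired(m, "treatment")
        assert out["t"].iloc[0] == pytest.approx(-3.674, abs=1e-3)
        assert out["p_ttest"].iloc[0] == pytest.approx(0.0213, abs=1e-3)

    def test_identical_groups_give_p_one(self):
        m = make_matrix([[7, 7, 7, 7, 7, 7]])
        out = ttest_unpaired(m, "treatment")
        assert out["t"].iloc[0] == 0.0
        assert out["p_ttest"].iloc[0] == 1.0

    def test_null_simulation_type_one_error(self):
        m, _ = gen_expression(n_genes=5000, de_fraction=0.0, sigma=0.25, seed=11)
        out = ttest_unpaired(m, "treatment")
        rate = (out["p_ttest"] < 0.01).mean()
        assert 0.005 <= rate <= 0.02


class TestRankProduct:
    def test_exact_enumeration_matches_one_ninth(self):
        """A gene ranked first in both of k=2 comparisons among n=3 genes has
        RP = 1 and exact p = 1/9 (full enumeration of rank tuples)."""
        m = make_matrix(
            [[8.0, 8.0, 1.0, 1.0], [4.0, 4.0, 2.0, 2.0], [1.0, 1.0, 4.0, 4.0]],
            n_drought=2,
            n_control=2,
        )
        out = rank_product(m, "treatment", exact=True)
        assert out["rp_up"].iloc[0] == 1.0
        assert out["p_up"].iloc[0] == pytest.approx(1 / 9)

    def test_worst_rank_gene(self):
        m = make_matrix(
            [[8.0, 8.0, 1.0, 1.0], [4.0, 4.0, 2.0, 2.0], [1.0, 1.0, 4.0, 4.0]],
            n_drought=2,
            n_control=2,
        )
        out = rank_product(m, "treatment", exact=True)
        assert out["rp_up"].iloc[-1] == pytest.approx(3.0)
        assert out["p_up"].iloc[-1] == pytest.approx(1.0)
        # symmetry: the worst up-regulated gene is the best down-regulated
        assert out["rp_down"].iloc[-1] == pytest.approx(1.0)

    def test_exact_p_equals_brute_force_enumeration(self):
        """Exact p for every gene equals a directly coded enumeration of all
        n^k equally likely rank tuples."""
        rng = np.random.default_rng(67)
        m = make_matrix(
            rng.lognormal(4, 0.4, size=(4, 4)), n_drought=2, n_control=2
        )
        out = rank_product(m, "treatment", exact=True)
        n, k = 4, 2
        tuples = list(itertools.product(range(1, n + 1), repeat=k))
        for gi in range(n):
            rp = out["rp_up"].iloc[gi]
            want = sum(
                1 for tup in tuples if np.prod(tup) ** (1 / k) <= rp * (1 + 1e-12)
            ) / len(tuples)
            assert out["p_up"].iloc[gi] == pytest.approx(want)

    def test_null_type_one_error_and_uniformity(self):
        m, _ = gen_expression(n_genes=5000, de_fraction=0.0, sigma=0.25, seed=11)
        out = rank_product(m, "treatment")
        rate = (out["p_up"] < 0.01).mean()
        assert 0.005 <= rate <= 0.02
        assert sps.kstest(out["p_up"], "uniform").pvalue > 0.01


class TestFisherCounts:
    def test_disjoint_table_p(self):
        # per-gene table [[5,0],[0,5]]: two-sided p = 2/252
        m = make_matrix([[5, 5, 5, 0, 0, 0], [0, 0, 0, 5, 5, 5]])
        m.values.iloc[0] = [3, 1, 1, 0, 0, 0]
        m.values.iloc[1] = [0, 0, 0, 4, 1, 0]
        p = fisher_counts(m, "treatment")
        assert p.iloc[0] == pytest.approx(2 / 252)

    def test_balanced_table_p_one(self):
        m = make_matrix([[1, 0, 0, 1, 0, 0], [1, 0, 0, 1, 0, 0]])
        p = fisher_counts(m, "treatment")
        assert (p == 1.0).all()

    def test_non_integer_input_rejected(self):
        m = make_matrix([[1.5, 2, 2, 2, 2, 2]])
        with pytest.raises(ValueError, match="integer"):
            fisher_counts(m, "treatment")

    def test_p_equals_full_margin_enumeration(self):
        """Fisher p for 200 random small tables equals the exhaustive sum of
        hypergeometric probabilities <= the observed table's probability."""
        rng = np.random.default_rng(71)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            p_got = sps.fisher_exact([[a, b], [c, d]], "two-sided")[1]
            # enumerate all tables with the same margins
            r1, r2 = a + b, c + d
            c1 = a + c
            n = r1 + r2
            def table_p(x):
                return (
                    comb(r1, x, exact=True)
                    * comb(r2, c1 - x, exact=True)
                    / comb(n, c1, exact=True)
                )
            obs = table_p(a)
            p_want = sum(
                table_p(x)
                for x in range(max(0, c1 - r2), min(r1, c1) + 1)
                if table_p(x) <= obs * (1 + 1e-9)
            )
            assert p_got == pytest.approx(p_want, rel=1e-6)


class TestBhFdr:
    def test_hand_step_up_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_matches_hand_rule_on_random_vectors(self):
        rng = np.random.default_rng(73)
        for _ in range(20):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 40)))
            got = bh_fdr(p)
            m = len(p)
            order = np.argsort(p)
            q_sorted = np.minimum.accumulate(
                (p[order] * m / np.arange(1, m + 1))[::-1]
            )[::-1]
            want = np.empty(m)
            want[order] = np.minimum(q_sorted, 1.0)
            assert got == pytest.approx(want)
            # q never below p; monotone in sorted order
            assert (got >= p - 1e-12).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestConsensus:
    def test_intersection_and_union(self):
        out = consensus(
            {"t": {"a", "b"}, "r": {"b", "c"}, "f": {"b"}}, ["a", "b", "c", "d"]
        )
        assert out["intersection"] == {"b"}
        assert out["union"] == {"a", "b", "c"}
        assert out["supported_by"]["b"] == frozenset({"t", "r", "f"})
        assert out["pairwise_overlap"][("f", "r")] == 1

    def test_empty_set_empties_intersection(self):
        out = consensus({"t": {"a"}, "r": set()}, ["a"])
        assert out["intersection"] == set()

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            consensus({"t": {"zz"}}, ["a"])

    def test_planted_signal_recovered_by_consensus(self):
        """Strongly planted genes (4-fold, n=4/group) land in the three-test
        intersection with at most one false positive."""
        m, truth = gen_expression(
            n_genes=400, de_fraction=0.025, log2fc=2.0, sigma=0.25, seed=79
        )
        table, cons = de_analysis(m, "treatment")
        planted = set(truth.de_genes)
        assert len(planted) == 10
        inter = cons["intersection"]
        assert planted <= inter
        assert len(inter - planted) <= 1

    def test_tissue_grouping_compares_within_drought_arm(self):
        rng = np.random.default_rng(83)
        m = make_matrix(
            rng.lognormal(4, 0.3, size=(20, 16)), n_drought=8, n_control=8,
            tissues=("root", "shoot"),
        )
        a, b = m.groups("tissue")
        meta = m.sample_meta
        assert set(meta.loc[a.columns, "treatment"]) == {"drought"}
        assert set(meta.loc[b.columns, "treatment"]) == {"drought"}
        assert set(meta.loc[a.columns, "tissue"]) == {"root"}
        assert set(meta.loc[b.columns, "tissue"]) == {"shoot"}
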