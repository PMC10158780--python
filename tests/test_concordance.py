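"""Concordance statistics against brute-force oracles: Spearman permutation
p-values, Mann-Whitney AUC, step-curve sensitivity, direction agreement and
Fisher's exact test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cfchip.concordance import (
    agreement_analysis,
    fisher_exact_2x2,
    roc_active_genes,
    sensitivity_at_specificity,
    spearman,
)


def brute_force_auc(scores, labels):
    """O(n1*n0) pairwise count with ties worth one half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def enumerate_spearman_p(x, y):
    """Exhaustive two-sided permutation p using an unrelated code path
    (per-permutation Pearson on ranks via scipy)."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho_obs = stats.pearsonr(rx, ry).statistic
    hits = total = 0
    for perm in itertools.permutations(rx):
        rho = stats.pearsonr(np.array(perm), ry).statistic
        if abs(rho) >= abs(rho_obs) - 1e-12:
            hits += 1
        total += 1
    return hits / total


def enumerate_fisher_p(table):
    """Full enumeration with math.comb only."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)

    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        if prob(x) <= p_obs * (1 + 1e-7)
    )


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)

    def test_perfect_antitone(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [50, 40, 30, 20, 10])
        assert rho == pytest.approx(-1.0)

    def test_exact_p_matches_enumeration_n5(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 3, 5, 4]  # rho = 0.7 class instance
        rho, p = spearman(x, y)
        assert p == pytest.approx(enumerate_spearman_p(x, y), abs=1e-12)

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_exact_p_matches_enumeration_random(self, n, rng):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        _, p = spearman(x, y)
        assert p == pytest.approx(enumerate_spearman_p(x, y), abs=1e-12)

    def test_large_n_agrees_with_scipy(self, rng):
        x = rng.normal(size=80)
        y = x + rng.normal(size=80)
        rho, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="undefined correlation"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestRoc:
    def test_perfect_separation(self):
        roc = roc_active_genes([10, 9, 1, 2], [True, True, False, False])
        assert roc.auc == 1.0
        assert roc.p_value == 0.0

    def test_all_ties_give_half(self):
        roc = roc_active_genes([3, 3, 3, 3], [True, True, False, False])
        assert roc.auc == 0.5

    def test_three_of_four_pairs_concordant(self):
        roc = roc_active_genes([3, 1, 2, 0], [True, True, False, False])
        assert roc.auc == pytest.approx(0.75)

    def test_matches_brute_force_pair_count(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 50))
            scores = rng.integers(0, 10, size=n).astype(float)  # many ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            roc = roc_active_genes(scores, labels)
            assert roc.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=200)
        labels = rng.random(200) < 0.4
        roc = roc_active_genes(scores, labels)
        assert roc.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_score_negation_complements_auc(self, rng):
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.5
        a = roc_active_genes(scores, labels).auc
        b = roc_active_genes(-scores, labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_hanley_mcneil_z_test(self):
        roc = roc_active_genes(
            [5, 4, 1.5, 2.5, 2, 1], [True, True, True, False, False, False]
        )
        a, n1, n0 = roc.auc, 3, 3
        assert 0.5 < a < 1.0
        q1, q2 = a / (2 - a), 2 * a**2 / (1 + a)
        se = np.sqrt(
            (a * (1 - a) + (n1 - 1) * (q1 - a**2) + (n0 - 1) * (q2 - a**2)) / (n1 * n0)
        )
        assert roc.se == pytest.approx(se)
        assert roc.z == pytest.approx((a - 0.5) / se)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            roc_active_genes([1.0, 2.0], [True, True])

    def test_curve_spans_both_corners(self, rng):
        roc = roc_active_genes(rng.normal(size=30), rng.random(30) < 0.5)
        assert roc.curve[0] == (1.0, 0.0)
        assert roc.curve[-1] == (0.0, 1.0)


class TestSensitivityAtSpecificity:
    def test_perfect_separation_everywhere(self):
        roc = roc_active_genes([10, 9, 1, 2], [True, True, False, False])
        for cutoff in (0.1, 0.5, 0.75, 0.99):
            assert sensitivity_at_specificity(roc, cutoff) == 1.0

    def test_identical_distributions_bounded(self):
        roc = roc_active_genes(
            [1, 2, 3, 4, 1, 2, 3, 4],
            [True, True, True, True, False, False, False, False],
        )
        # only the top-score threshold reaches specificity >= 0.75; it also
        # calls 1 of 4 active genes
        assert sensitivity_at_specificity(roc, 0.75) == pytest.approx(0.25)

    def test_zero_cutoff_gives_max_sensitivity(self, rng):
        roc = roc_active_genes(rng.normal(size=20), rng.random(20) < 0.5)
        assert sensitivity_at_specificity(roc, 0.0) == 1.0


def make_de(n_up_a=0, n_up_b=0):
    genes = [f"a{i}" for i in range(n_up_a)] + [f"b{i}" for i in range(n_up_b)]
    status = ["up_in_a"] * n_up_a + ["up_in_b"] * n_up_b
    return pd.DataFrame({"gene_id": genes, "status": status}).set_index(
        "gene_id", drop=False
    )


class TestAgreement:
    def test_eleven_of_thirteen_concordant(self):
        de = make_de(n_up_a=13)
        fc = pd.Series(
            [1.0] * 11 + [-1.0] * 2, index=[f"a{i}" for i in range(13)]
        )
        res = agreement_analysis(de, fc)
        assert round(res.sensitivity_a, 2) == 0.85
        assert res.contingency[0].tolist() == [11, 2]

    def test_fully_concordant_down_direction(self):
        de = make_de(n_up_b=10)
        fc = pd.Series([-0.5] * 10, index=[f"b{i}" for i in range(10)])
        res = agreement_analysis(de, fc)
        assert res.sensitivity_b == 1.0

    def test_zero_fold_change_counts_as_disagreement(self):
        de = make_de(n_up_a=2)
        fc = pd.Series([2.0, 0.0], index=["a0", "a1"])
        res = agreement_analysis(de, fc)
        assert res.sensitivity_a == pytest.approx(0.5)

    def test_missing_enrichment_rejected(self):
        de = make_de(n_up_a=2)
        fc = pd.Series([2.0], index=["a0"])
        with pytest.raises(ValueError, match="missing enrichment"):
            agreement_analysis(de, fc)

    def test_balanced_table_fisher_p_is_one(self):
        de = make_de(n_up_a=10, n_up_b=10)
        fc = pd.Series(
            [1.0] * 5 + [-1.0] * 5 + [1.0] * 5 + [-1.0] * 5,
            index=list(de["gene_id"]),
        )
        res = agreement_analysis(de, fc)
        assert res.contingency.tolist() == [[5, 5], [5, 5]]
        assert res.fisher_p == pytest.approx(1.0)


class TestFisherExact:
    def test_balanced_table(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_diagonal_table_closed_form(self):
        expected = 2 / math.comb(20, 10)
        assert fisher_exact_2x2([[10, 0], [0, 10]]) == pytest.approx(expected, rel=1e-12)

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(100):
            t = rng.integers(0, 16, size=(2, 2))
            if t.sum() == 0:
                continue
            assert fisher_exact_2x2(t) == pytest.approx(
                enumerate_fisher_p(t), abs=1e-12
            )

    def test_matches_scipy_cross_check(self, rng):
        for _ in range(30):
            t = rng.integers(0, 30, size=(2, 2))
            if t.sum() == 0:
                continue
            assert fisher_exact_2x2(t) == pytest.approx(
                stats.fisher_exact(t).pvalue, rel=1e-9
            )

    def test_invariance_under_transpose_and_double_swap(self, rng):
        t = rng.integers(0, 12, size=(2, 2)) + 1
        p = fisher_exact_2x2(t)
        assert fisher_exact_2x2(t.T) == pytest.approx(p, abs=1e-12)
        assert fisher_exact_2x2(t[::-1, ::-1]) == pytest.approx(p, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            fisher_exact_2x2([[0, 0], [0, 0]])
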