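"""Validation statistics: AUC, DeLong, Fisher 2x2, rank-interval enrichment,
evidence CDF, stepwise hypergeometric curve."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

import targetrank as tr
from targetrank.evaluate import interval_sizes


class TestAuc:
    def test_perfect_separation(self):
        assert tr.auc_score([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_random_scores_near_half(self, rng):
        scores = rng.random(2000)
        labels = rng.integers(0, 2, 2000)
        assert tr.auc_score(scores, labels) == pytest.approx(0.5, abs=0.03)

    def test_equals_mann_whitney_u(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            scores = rng.normal(size=n)
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            n1, n0 = labels.sum(), n - labels.sum()
            u = stats.mannwhitneyu(
                scores[labels == 1], scores[labels == 0], alternative="two-sided"
            ).statistic
            assert tr.auc_score(scores, labels) == pytest.approx(u / (n1 * n0))

    def test_ties_count_half(self):
        assert tr.auc_score([0.5, 0.5], [0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(tr.InputError):
            tr.auc_score([0.1, 0.2], [1, 1])


class TestDeLong:
    def test_identical_scores_p_one(self, rng):
        s = rng.random(100)
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        auc_a, auc_b, p = tr.delong_test(s, s, y)
        assert auc_a == auc_b
        assert p == 1.0

    def test_symmetry_under_swap(self, rng):
        y = np.repeat([0, 1], 60)
        a = rng.normal(y, 1.0)
        b = rng.normal(y, 2.0)
        _, _, p_ab = tr.delong_test(a, b, y)
        _, _, p_ba = tr.delong_test(b, a, y)
        assert p_ab == pytest.approx(p_ba)

    def test_reduces_to_auc_score(self, rng):
        y = np.repeat([0, 1], 50)
        a = rng.normal(y, 1.0)
        b = rng.normal(y, 0.5)
        auc_a, auc_b, _ = tr.delong_test(a, b, y)
        assert auc_a == pytest.approx(tr.auc_score(a, y))
        assert auc_b == pytest.approx(tr.auc_score(b, y))

    def test_detects_clear_auc_difference(self, rng):
        y = np.repeat([0, 1], 150)
        a = rng.normal(2.0 * y, 1.0)  # strong model
        b = rng.normal(size=300)      # uninformative model
        _, _, p = tr.delong_test(a, b, y)
        assert p < 1e-6

    def test_length_mismatch_rejected(self):
        with pytest.raises(tr.InputError):
            tr.delong_test([0.1], [0.2, 0.3], [0, 1])


def exhaustive_fisher_p(a, b, c, d):
    """Oracle: enumerate the hypergeometric support, sum outcomes with
    probability <= the observed table's."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_balanced_table_is_null(self):
        odds, p = tr.fisher_2x2(1, 1, 1, 1)
        assert odds == 1.0
        assert p == 1.0

    def test_matches_exhaustive_enumeration_on_fixed_margins(self):
        # all tables with margins (5,5,5,5)
        for a in range(6):
            b, c, d = 5 - a, 5 - a, a
            odds, p = tr.fisher_2x2(a, b, c, d)
            assert p == pytest.approx(exhaustive_fisher_p(a, b, c, d), rel=1e-9)

    def test_matches_enumeration_on_random_small_tables(self, rng):
        for _ in range(30):
            a, b, c, d = (int(x) for x in rng.integers(0, 11, 4))
            if a + b == 0 or c + d == 0:
                continue
            _, p = tr.fisher_2x2(a, b, c, d)
            assert p == pytest.approx(exhaustive_fisher_p(a, b, c, d), rel=1e-9)

    def test_haldane_correction_only_with_zero_cell(self):
        odds, _ = tr.fisher_2x2(0, 10, 5, 5)
        assert odds == pytest.approx(0.5 * 5.5 / (10.5 * 5.5))
        odds2, _ = tr.fisher_2x2(2, 10, 5, 5)
        assert odds2 == pytest.approx(2 * 5 / (10 * 5))

    def test_row_column_swap_invariances(self, rng):
        a, b, c, d = 3, 7, 6, 4
        odds, p = tr.fisher_2x2(a, b, c, d)
        # simultaneous row and column swap: p and OR invariant
        odds_sw, p_sw = tr.fisher_2x2(d, c, b, a)
        assert p_sw == pytest.approx(p)
        assert odds_sw == pytest.approx(odds)
        # single row swap inverts the OR
        odds_row, p_row = tr.fisher_2x2(c, d, a, b)
        assert odds_row == pytest.approx(1 / odds)
        assert p_row == pytest.approx(p)

    def test_empty_row_rejected(self):
        with pytest.raises(tr.InputError):
            tr.fisher_2x2(0, 0, 3, 4)
        with pytest.raises(tr.InputError):
            tr.fisher_2x2(1, 2, -1, 4)


class TestRankIntervalEnrichment:
    def test_evidence_concentrated_in_top_interval(self):
        ranking = [f"g{i}" for i in range(100)]
        evidence = set(ranking[:5])  # exactly the first interval at B=20
        table = tr.rank_interval_enrichment(ranking, evidence, B=20)
        assert table.loc[0, "n_with_evidence"] == 5
        assert (table.loc[1:, "n_with_evidence"] == 0).all()
        assert table.loc[0, "odds_ratio"] == table["odds_ratio"].max()
        assert table.loc[0, "p_value"] < 1e-6

    def test_counts_conserve_evidence_and_universe(self, rng):
        ranking = [f"g{i}" for i in range(517)]
        evidence = set(rng.choice(ranking, 60, replace=False))
        table = tr.rank_interval_enrichment(ranking, evidence, B=20)
        assert table["n_with_evidence"].sum() == len(evidence)
        assert table["n_genes"].sum() == len(ranking)
        assert (table["odds_ratio"] >= 0).all()

    def test_null_evidence_or_near_one(self):
        medians = []
        ranking = [f"g{i}" for i in range(2000)]
        for seed in range(50):
            local = np.random.default_rng(seed)
            evidence = set(local.choice(ranking, 200, replace=False))
            table = tr.rank_interval_enrichment(ranking, evidence, B=20)
            medians.append(table["odds_ratio"].median())
        assert 0.7 <= float(np.median(medians)) <= 1.4

    def test_interval_sizes_near_equal(self):
        sizes = interval_sizes(103, 20)
        assert sum(sizes) == 103
        assert set(sizes) == {5, 6}
        assert max(sizes) - min(sizes) == 1

    def test_bad_inputs(self):
        with pytest.raises(tr.InputError):
            tr.rank_interval_enrichment(["a", "b"], set(), B=5)
        with pytest.raises(tr.InputError):
            tr.rank_interval_enrichment(["a", "b", "c"], {"zzz"}, B=2)


class TestEvidenceCdf:
    def test_top_concentrated_cdf_saturates_immediately(self):
        ranking = [f"g{i}" for i in range(100)]
        cdf = tr.evidence_cdf(ranking, set(ranking[:5]), B=20)
        assert cdf[0] == 1.0
        assert (cdf == 1.0).all()

    def test_uniform_evidence_cdf_linear(self, rng):
        ranking = [f"g{i}" for i in range(2000)]
        evidence = set(rng.choice(ranking, 400, replace=False))
        cdf = tr.evidence_cdf(ranking, evidence, B=20)
        expected = np.arange(1, 21) / 20
        assert np.abs(cdf - expected).max() < 0.08

    def test_monotone_and_ends_at_one(self, rng):
        ranking = [f"g{i}" for i in range(150)]
        evidence = set(rng.choice(ranking, 30, replace=False))
        cdf = tr.evidence_cdf(ranking, evidence, B=10)
        assert (np.diff(cdf) >= 0).all()
        assert cdf[-1] == 1.0

    def test_empty_evidence_rejected(self):
        with pytest.raises(tr.InputError):
            tr.evidence_cdf(["a", "b"], set(), B=2)


def hypergeom_tail_oracle(overlap, n, K, k):
    """Direct tail sum of the hypergeometric pmf."""
    return sum(
        math.comb(K, x) * math.comb(n - K, k - x) / math.comb(n, k)
        for x in range(overlap, min(K, k) + 1)
    )


class TestStepwiseHypergeom:
    def test_reference_equal_to_top_k_minimises_p_at_k(self, rng):
        ranking = [f"g{i}" for i in range(100)]
        reference = set(ranking[:20])
        curve = tr.stepwise_hypergeom(ranking, reference, step=10)
        k_idx = list(curve.cutoffs).index(20)
        assert curve.pvalues[k_idx] == curve.pvalues.min()

    def test_matches_direct_tail_sums_small_universe(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 51))
            ranking = [f"g{i}" for i in range(n)]
            K = int(rng.integers(2, n // 2 + 1))
            reference = set(rng.choice(ranking, K, replace=False))
            step = int(rng.integers(1, 8))
            curve = tr.stepwise_hypergeom(ranking, reference, step=step)
            in_ref = np.cumsum([g in reference for g in ranking])
            for k, p in zip(curve.cutoffs, curve.pvalues):
                oracle = hypergeom_tail_oracle(int(in_ref[k - 1]), n, K, k)
                assert p == pytest.approx(oracle, rel=1e-9, abs=1e-12)

    def test_null_reference_auc_mostly_zero(self):
        zeros = 0
        ranking = [f"g{i}" for i in range(1000)]
        for seed in range(50):
            local = np.random.default_rng(seed)
            reference = set(local.choice(ranking, 50, replace=False))
            curve = tr.stepwise_hypergeom(ranking, reference, step=50)
            zeros += curve.enriched_auc == 0.0
        assert zeros >= 40  # >= 80% of seeds

    def test_auc_monotone_under_top_concentration(self):
        ranking = [f"g{i}" for i in range(400)]
        # nested references increasingly concentrated at the top
        aucs = []
        for frac_top in (0.2, 0.5, 0.8, 1.0):
            n_top = int(40 * frac_top)
            reference = set(ranking[:n_top]) | set(ranking[200 : 200 + 40 - n_top])
            curve = tr.stepwise_hypergeom(ranking, reference, step=20)
            aucs.append(curve.enriched_auc)
        assert all(b >= a for a, b in zip(aucs, aucs[1:]))

    def test_final_cutoff_covers_whole_ranking(self):
        ranking = [f"g{i}" for i in range(55)]
        curve = tr.stepwise_hypergeom(ranking, set(ranking[:5]), step=10)
        assert curve.cutoffs[-1] == 55
        assert curve.pvalues[-1] == pytest.approx(1.0)

    def test_step_validation(self):
        with pytest.raises(tr.InputError):
            tr.stepwise_hypergeom(["a"], {"a"}, step=0)
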