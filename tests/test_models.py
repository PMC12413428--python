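"""Uniform and Yule-Harding shape distributions and index expectations."""

import math
from collections import Counter
from fractions import Fraction

import pytest

from conftest import clusters, labeled_trees
from gfbtree import (caterpillar, enumerate_shapes, fully_balanced, gfb,
                     s_hat, sackin, sample_yule, shape_probability)
from gfbtree.models import (cluster_probability_uniform,
                            expected_index_by_enumeration,
                            expected_index_monte_carlo,
                            expected_s_hat_uniform,
                            expected_sackin_cluster_sum,
                            expected_sackin_uniform, s_hat_uniform_bounds,
                            s_hat_uniform_printed_sum, shape_distribution,
                            yule_phylo_probability)
from gfbtree.tree_core import count_labelings


class TestProbabilities:
    def test_yule_phylo_examples(self):
        assert yule_phylo_probability(caterpillar(2)) == 1
        assert yule_phylo_probability(caterpillar(4)) == Fraction(1, 18)
        assert yule_phylo_probability(fully_balanced(2)) == Fraction(1, 9)

    def test_shape_probability_examples(self):
        assert shape_probability(caterpillar(4), "uniform") == \
            Fraction(12, 15)
        assert shape_probability(caterpillar(4), "yule") == Fraction(2, 3)
        with pytest.raises(ValueError, match="unknown model"):
            shape_probability(caterpillar(4), "pda")

    @pytest.mark.parametrize("model", ["uniform", "yule"])
    @pytest.mark.parametrize("n", range(2, 11))
    def test_normalization_is_exact(self, n, model):
        dist = shape_distribution(n, model)
        assert sum(dist.probabilities.values()) == Fraction(1)
        assert all(p > 0 for p in dist.probabilities.values())

    @pytest.mark.parametrize("n", range(2, 11))
    def test_yule_per_tree_probabilities_sum_to_one(self, n):
        total = sum(count_labelings(t) * yule_phylo_probability(t)
                    for t in enumerate_shapes(n))
        assert total == Fraction(1)


class TestClusterProbability:
    @pytest.mark.parametrize("n", range(4, 8))
    def test_matches_brute_force_over_labeled_trees(self, n):
        trees = labeled_trees(n)
        for k in range(1, n + 1):
            fixed = frozenset(range(k))
            hits = sum(1 for t in trees if fixed in clusters(t))
            assert cluster_probability_uniform(n, k) == \
                Fraction(hits, len(trees))

    def test_boundary_values(self):
        assert cluster_probability_uniform(4, 1) == 1
        assert cluster_probability_uniform(4, 4) == 1
        assert cluster_probability_uniform(4, 2) == Fraction(1, 5)
        assert cluster_probability_uniform(4, 3) == Fraction(1, 5)
        with pytest.raises(ValueError):
            cluster_probability_uniform(4, 5)


class TestExpectations:
    @pytest.mark.parametrize("n", range(2, 11))
    def test_sackin_closed_form_equals_enumeration_exactly(self, n):
        dist = shape_distribution(n, "uniform")
        exact = sum(p * sackin(t) for t, p in dist.probabilities.items())
        assert exact == expected_sackin_uniform(n)

    @pytest.mark.parametrize("n", range(2, 13))
    def test_sackin_cluster_sum_identity(self, n):
        # the k = 1 term exactly offsets the omitted k = n root term
        assert expected_sackin_cluster_sum(n) == expected_sackin_uniform(n)

    def test_sackin_small_values(self):
        assert expected_sackin_uniform(2) == 2
        assert expected_sackin_uniform(3) == 5
        assert expected_sackin_uniform(4) == Fraction(44, 5)

    @pytest.mark.parametrize("n", range(2, 11))
    def test_s_hat_cluster_formula_equals_enumeration(self, n):
        oracle = expected_index_by_enumeration(n, s_hat, "uniform")
        assert expected_s_hat_uniform(n) == pytest.approx(oracle, abs=1e-12)

    def test_printed_sum_misses_exactly_the_root_term(self):
        # the truncated cluster sum undershoots by log2(n - 1); at n = 4 it
        # prints 0.8 where the true expectation is 2.38496...
        oracle = expected_index_by_enumeration(4, s_hat, "uniform")
        printed = s_hat_uniform_printed_sum(4)
        assert printed == pytest.approx(0.8)
        assert oracle - printed == pytest.approx(math.log2(3), abs=1e-12)

    @pytest.mark.parametrize("n", range(2, 11))
    def test_upper_bound_holds_lower_bound_reported_only(self, n):
        rep = s_hat_uniform_bounds(n)
        assert rep.exact_below_upper  # s-hat <= Sackin pointwise
        if n == 4:  # documented counterexample to the printed lower bound
            assert rep.lower == pytest.approx(4.4)
            assert rep.exact == pytest.approx(2.3849625, abs=1e-6)
            assert not rep.exact_above_lower


class TestYuleSampling:
    def test_degenerate_sizes_are_deterministic(self):
        assert sample_yule(1, seed=0).leaf_count == 1
        for seed in range(5):
            assert sample_yule(3, seed=seed) is caterpillar(3)

    def test_four_leaf_frequencies_match_exact_yule(self):
        reps = 20_000
        import random
        rng = random.Random(42)
        hits = sum(sample_yule(4, rng) is caterpillar(4)
                   for _ in range(reps))
        p = Fraction(2, 3)
        se = math.sqrt(float(p * (1 - p)) / reps)
        assert abs(hits / reps - float(p)) < 4 * se

    def test_monte_carlo_agrees_with_enumeration(self):
        exact = expected_index_by_enumeration(4, s_hat, "yule")
        assert exact == pytest.approx(
            float(Fraction(2, 3)) * math.log2(6) +
            float(Fraction(1, 3)) * math.log2(3))
        mean, se = expected_index_monte_carlo(4, s_hat, 20_000, seed=7)
        assert abs(mean - exact) < 4 * se

    def test_degenerate_monte_carlo(self):
        mean, se = expected_index_monte_carlo(3, sackin, 50, seed=0)
        assert mean == 5.0 and se == 0.0

    def test_enumeration_refuses_large_n(self):
        with pytest.raises(ValueError, match="impractical"):
            expected_index_by_enumeration(30, sackin, "uniform")

    @pytest.mark.parametrize("model", ["uniform", "yule"])
    def test_expectation_lies_between_extremes(self, model):
        n = 8
        val = expected_index_by_enumeration(n, s_hat, model)
        assert s_hat(gfb(n)) < val < s_hat(caterpillar(n))
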