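import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import beta as beta_dist

from betadce import (
    DegenerateFeatureError,
    FeatureLookupError,
    FeatureMatrix,
    ValidationError,
    beta_expectation,
    beta_variance,
    evaluate_subset,
    neighbor_profile,
    optimize_sample_k,
    subset_entropy,
)

from ._reference import naive_entropy, naive_neighbor_order
from .conftest import random_matrix


class TestBetaExpectation:
    @pytest.mark.parametrize(
        "k_a,k_b,e_a",
        [(0, 0, 0.5), (3, 1, 4 / 6), (6, 2, 0.7), (1, 0, 2 / 3), (0, 5, 1 / 7)],
    )
    def test_closed_form(self, k_a, k_b, e_a):
        got_a, got_b = beta_expectation(k_a, k_b)
        assert got_a == pytest.approx(e_a, abs=1e-15)
        assert got_a + got_b == pytest.approx(1.0, abs=1e-15)

    @given(st.integers(0, 500), st.integers(0, 500))
    @settings(deadline=None, max_examples=200)
    def test_normalized_pair_in_open_interval(self, k_a, k_b):
        e_a, e_b = beta_expectation(k_a, k_b)
        assert e_a + e_b == pytest.approx(1.0, abs=1e-15)
        assert 0.0 < e_a < 1.0 and 0.0 < e_b < 1.0

    @given(st.integers(0, 100), st.integers(0, 100))
    @settings(deadline=None, max_examples=100)
    def test_monotone_in_counts(self, k_a, k_b):
        e_a, _ = beta_expectation(k_a, k_b)
        assert beta_expectation(k_a + 1, k_b)[0] > e_a
        assert beta_expectation(k_a, k_b + 1)[0] < e_a

    @pytest.mark.parametrize("bad", [(-1, 0), (0, -2), (1.5, 0), (0, 2.3)])
    def test_rejects_invalid_counts(self, bad):
        with pytest.raises(ValidationError):
            beta_expectation(*bad)
        with pytest.raises(ValidationError):
            beta_variance(*bad)


class TestBetaVariance:
    def test_uniform_prior_variance(self):
        assert beta_variance(0, 0) == pytest.approx(1 / 12, abs=1e-15)

    def test_matches_numerical_integration(self):
        # independent oracle: second central moment of the Beta(4, 2) density
        mean = quad(lambda p: p * beta_dist.pdf(p, 4, 2), 0, 1)[0]
        var = quad(lambda p: (p - mean) ** 2 * beta_dist.pdf(p, 4, 2), 0, 1)[0]
        assert beta_variance(3, 1) == pytest.approx(var, abs=1e-10)
        assert beta_variance(3, 1) == pytest.approx(0.031746, abs=1e-6)

    def test_sharpens_at_fixed_ratio(self):
        assert beta_variance(6, 2) < beta_variance(3, 1)


class TestNeighborProfile:
    def test_monotone_distances(self, four_sample):
        profile = neighbor_profile(four_sample, ["f1"], 0)
        assert list(profile.ordered_neighbors) == [1, 2, 3]
        # prefix counts are consistent and non-decreasing
        counts = profile.cumulative_class_counts
        assert (counts.sum(axis=1) == np.arange(1, 4)).all()
        assert (np.diff(counts, axis=0) >= 0).all()

    def test_ties_break_toward_lower_index(self):
        matrix = FeatureMatrix(
            values=np.array([[0.0], [5.0], [5.0], [5.0]]),
            labels=np.array(["A", "B", "A", "B"]),
            feature_names=("f1",),
        )
        profile = neighbor_profile(matrix, ["f1"], 0)
        assert list(profile.ordered_neighbors) == [1, 2, 3]

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(42)
        matrix = random_matrix(rng, 10, 3)
        for i in range(10):
            got = list(neighbor_profile(matrix, matrix.feature_names, i).ordered_neighbors)
            assert got == naive_neighbor_order(matrix.values.tolist(), i)

    def test_unknown_feature_rejected(self, four_sample):
        with pytest.raises(FeatureLookupError):
            neighbor_profile(four_sample, ["nope"], 0)


class TestOptimizeSampleK:
    def test_tight_pair_prefers_k1(self, four_sample):
        profile = neighbor_profile(four_sample, ["f1"], 0)
        se = optimize_sample_k(profile, "A")
        assert (se.K, se.K_a, se.K_b) == (1, 1, 0)
        assert se.E == pytest.approx(2 / 3)

    def test_pure_same_class_run_extends_k(self):
        # E strictly increases along a pure same-class run, so the scan
        # takes the whole run: sample 0's nearest 2 neighbors are both A.
        matrix = FeatureMatrix(
            values=np.arange(5, dtype=float).reshape(-1, 1),
            labels=np.array(["A", "A", "A", "B", "B"]),
            feature_names=("f1",),
        )
        profile = neighbor_profile(matrix, ["f1"], 0)
        se = optimize_sample_k(profile, "A")
        assert se.K == 2 and se.E == pytest.approx(3 / 4)

    def test_alternating_labels_balance_at_k2(self, alternating):
        profile = neighbor_profile(alternating, ["f1"], 0)
        se = optimize_sample_k(profile, "A")
        # exhaustive: E(1)=1/3, E(2)=2/4, E(3)=2/5
        assert se.K == 2 and se.E == pytest.approx(0.5)

    def test_k_max_out_of_range(self, four_sample):
        profile = neighbor_profile(four_sample, ["f1"], 0)
        with pytest.raises(ValidationError):
            optimize_sample_k(profile, "A", k_max=10)


class TestEvaluateSubset:
    def test_worked_example(self, four_sample):
        result = evaluate_subset(four_sample, ["f1"])
        assert result.H == pytest.approx(2 * math.log(1.5), abs=1e-12)
        assert all(s.E == pytest.approx(2 / 3) for s in result.per_sample)

    def test_label_swap_invariance(self, xor_matrix):
        swapped = FeatureMatrix(
            values=xor_matrix.values,
            labels=np.where(xor_matrix.labels == "A", "B", "A"),
            feature_names=xor_matrix.feature_names,
        )
        h = subset_entropy(xor_matrix, ["f1", "f2"])
        assert subset_entropy(swapped, ["f1", "f2"]) == pytest.approx(h, abs=1e-12)

    def test_matches_brute_force_reference(self):
        rng = np.random.default_rng(7)
        matrix = random_matrix(rng, 20, 4)
        got = evaluate_subset(matrix, matrix.feature_names).H
        want = naive_entropy(matrix.values.tolist(), list(matrix.labels))
        assert got == pytest.approx(want, abs=1e-12)

    def test_entropy_lower_bound(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            matrix = random_matrix(rng, int(rng.integers(5, 20)), 3)
            h = subset_entropy(matrix, matrix.feature_names)
            bound = -math.log(matrix.n_a / (matrix.n_a + 1)) - math.log(
                matrix.n_b / (matrix.n_b + 1)
            )
            assert h >= bound - 1e-12

    def test_degenerate_feature_rejected(self):
        matrix = FeatureMatrix(
            values=np.array([[0.0, 1.0], [1.0, 1.0], [2.0, 1.0], [3.0, 1.0]]),
            labels=np.array(["A", "A", "B", "B"]),
            feature_names=("f1", "flat"),
        )
        with pytest.raises(DegenerateFeatureError):
            evaluate_subset(matrix, ["f1", "flat"])

    def test_predicted_class_objective_never_exceeds_true_class(self, xor_matrix):
        # max(E_A, E_B) >= E_true pointwise, so its cross-entropy is never larger
        h_true = subset_entropy(xor_matrix, ["f1"], objective="true-class")
        h_pred = subset_entropy(xor_matrix, ["f1"], objective="predicted-class")
        assert h_pred <= h_true + 1e-12

    def test_deterministic_repeat(self, xor_matrix):
        a = evaluate_subset(xor_matrix, ["f1", "f2"])
        b = evaluate_subset(xor_matrix, ["f1", "f2"])
        assert a.H == b.H
        assert (a.sample_K == b.sample_K).all()


class TestFeatureMatrixValidation:
    def test_rejects_nan(self):
        with pytest.raises(ValidationError, match="non-finite"):
            FeatureMatrix(
                values=np.array([[0.0], [np.nan], [1.0], [2.0]]),
                labels=np.array(["A", "A", "B", "B"]),
                feature_names=("f1",),
            )

    def test_rejects_singleton_class(self):
        with pytest.raises(ValidationError, match="at least two"):
            FeatureMatrix(
                values=np.zeros((3, 1)),
                labels=np.array(["A", "B", "B"]),
                feature_names=("f1",),
            )

    def test_rejects_duplicate_feature_names(self):
        with pytest.raises(ValidationError, match="unique"):
            FeatureMatrix(
                values=np.zeros((4, 2)),
                labels=np.array(["A", "A", "B", "B"]),
                feature_names=("f1", "f1"),
            )
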