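"""Review curves, improvement over random, review efficiency."""

import itertools

import numpy as np
import pytest

from deepaction.review import (
    accuracy_after_review,
    confidence_order,
    improvement_over_random,
    optimal_order,
    random_review_curve,
    review_curve,
    review_efficiency,
    review_summary,
)


class TestAccuracyAfterReview:
    def test_endpoints(self):
        accs, sizes = [0.5, 0.9], [10, 10]
        order = [0, 1]
        assert accuracy_after_review(accs, sizes, order, 0) == pytest.approx(0.7)
        assert accuracy_after_review(accs, sizes, order, 2) == 1.0

    def test_worst_first_single_review(self):
        assert accuracy_after_review([0.5, 0.9], [10, 10], [0, 1], 1) == (
            pytest.approx((1 + 0.9) / 2)
        )

    def test_best_first_single_review(self):
        assert accuracy_after_review([0.5, 0.9], [10, 10], [1, 0], 1) == (
            pytest.approx((0.5 + 1) / 2)
        )

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            accuracy_after_review([0.5], [10], [0], 2)

    def test_curve_matches_pointwise_formula(self):
        rng = np.random.default_rng(0)
        accs = rng.random(8)
        sizes = rng.integers(5, 50, 8)
        order = rng.permutation(8)
        curve = review_curve(accs, sizes, order)
        for k in range(9):
            assert curve.acc_k[k] == pytest.approx(
                accuracy_after_review(accs, sizes, order, k)
            )


class TestCurveProperties:
    def test_non_decreasing_and_bounded(self):
        rng = np.random.default_rng(1)
        accs = rng.random(10)
        sizes = rng.integers(1, 100, 10)
        for _ in range(5):
            curve = review_curve(accs, sizes, rng.permutation(10))
            assert np.all(np.diff(curve.acc_k) >= -1e-12)
            assert curve.acc_k[0] == pytest.approx(
                np.average(accs, weights=sizes)
            )
            assert curve.acc_k[-1] == 1.0

    def test_optimal_curve_dominates_all_orderings_exhaustively(self):
        """On every equal-size instance up to 6 clips, the
        ascending-accuracy order dominates every other ordering at every
        budget k.  (With unequal clip sizes the dominant order is by
        descending (1-acc)*size instead; the review framework sorts by
        accuracy, which is optimal for the equal-length clips it assumes.)"""
        rng = np.random.default_rng(2)
        for n in (3, 4, 5, 6):
            accs = rng.random(n)
            sizes = np.full(n, 10)
            opt = review_curve(accs, sizes, optimal_order(accs)).acc_k
            for perm in itertools.permutations(range(n)):
                other = review_curve(accs, sizes, np.array(perm)).acc_k
                assert np.all(opt >= other - 1e-12)


class TestRandomBaseline:
    def test_two_clip_exhaustive_expectation(self):
        curve = random_review_curve([0.5, 0.9], [10, 10])
        # k=1: mean of 0.95 (worst-first) and 0.75 (best-first)
        assert curve.acc_k[1] == pytest.approx(0.85)
        assert curve.acc_k[0] == pytest.approx(0.7)
        assert curve.acc_k[2] == 1.0

    def test_equal_sizes_closed_form(self):
        """E[acc(D_k)] = acc0 + (k/n)(1 - acc0) for equal-size clips."""
        rng = np.random.default_rng(3)
        accs = rng.random(10)
        curve = random_review_curve(accs, np.full(10, 7), n_permutations=400, seed=0)
        acc0 = accs.mean()
        expected = acc0 + np.arange(11) / 10 * (1 - acc0)
        # Monte-Carlo mean within 3 standard errors
        gains = (1 - accs) / 10
        se = 3 * np.std(gains) * np.sqrt(10) / np.sqrt(400)
        np.testing.assert_allclose(curve.acc_k, expected, atol=max(se, 1e-3))

    def test_endpoints_match_any_ordering(self):
        rng = np.random.default_rng(4)
        accs, sizes = rng.random(9), rng.integers(1, 30, 9)
        rand = random_review_curve(accs, sizes, n_permutations=50, seed=1)
        fixed = review_curve(accs, sizes, np.arange(9))
        assert rand.acc_k[0] == pytest.approx(fixed.acc_k[0])
        assert rand.acc_k[-1] == pytest.approx(1.0)


class TestIORAndEfficiency:
    def _setup(self):
        accs = np.array([0.5, 0.9])
        sizes = np.array([10.0, 10.0])
        rand = random_review_curve(accs, sizes)
        opt = review_curve(accs, sizes, optimal_order(accs))
        return accs, sizes, rand, opt

    def test_random_vs_itself_is_zero(self):
        _, _, rand, _ = self._setup()
        ior, mean_ior = improvement_over_random(rand, rand)
        np.testing.assert_allclose(ior, 0.0)
        assert mean_ior == 0.0

    def test_two_clip_optimal_ior(self):
        _, _, rand, opt = self._setup()
        ior, mean_ior = improvement_over_random(opt, rand)
        assert ior[1] == pytest.approx(0.95 - 0.85)
        assert ior[0] == ior[2] == pytest.approx(0.0)
        # (n+1)-term sum divided by n, as defined
        assert mean_ior == pytest.approx(0.10 / 2)

    def test_efficiency_of_optimal_order_is_one(self):
        accs, sizes, rand, opt = self._setup()
        _, mean_opt = improvement_over_random(opt, rand)
        assert review_efficiency(mean_opt, mean_opt) == 1.0

    def test_anti_sorted_order_is_negative(self):
        accs, sizes, rand, opt = self._setup()
        worst = review_curve(accs, sizes, optimal_order(accs)[::-1].copy())
        _, mean_worst = improvement_over_random(worst, rand)
        _, mean_opt = improvement_over_random(opt, rand)
        assert review_efficiency(mean_worst, mean_opt) < 0

    def test_flat_accuracies_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            review_efficiency(0.0, 0.0)


class TestReviewSummary:
    def test_confidence_matching_accuracy_order_gives_efficiency_one(self):
        rng = np.random.default_rng(5)
        accs = rng.permutation(np.linspace(0.3, 0.95, 10))
        sizes = np.full(10, 20)
        summary = review_summary(accs, sizes, confidences=accs, seed=0)
        assert summary.efficiency == pytest.approx(1.0)

    def test_random_scores_near_zero_well_calibrated_beats_shuffled(self):
        """Efficiency with calibrated scores exceeds label-shuffled scores."""
        rng = np.random.default_rng(6)
        accs = rng.uniform(0.4, 1.0, 12)
        sizes = rng.integers(10, 40, 12)
        conf = np.clip(accs + rng.normal(0, 0.03, 12), 0, 1)
        good = review_summary(accs, sizes, confidences=conf,
                              n_permutations=200, seed=1)
        shuffled = review_summary(accs, sizes,
                                  confidences=rng.permutation(conf),
                                  n_permutations=200, seed=1)
        assert good.efficiency > shuffled.efficiency

    def test_ties_broken_by_clip_index(self):
        order = confidence_order([0.5, 0.5, 0.2])
        assert order.tolist() == [2, 0, 1]
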