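"""Confidence-based review simulation: accuracy-vs-budget curves.

Reviewing a clip corrects all of its labels, raising its accuracy to 1.
Given an ordering of the n unlabeled clips, acc(D_k) is the frame-weighted
dataset accuracy after the first k clips are reviewed:

    acc(D_k) = |D_k^rev|/|D| + acc(D_k^unrev) · |D_k^unrev|/|D|.

The improvement over random, IOR_k = acc(D_k^order) − acc(D_k^random), is
averaged over k = 0..n (an (n+1)-term sum divided by n, as defined), and
the review efficiency is mean-IOR of the candidate ordering divided by
mean-IOR of the optimal (ascending-true-accuracy) ordering: 1 when the
candidate matches the optimal order, 0 in expectation for a random order.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReviewCurve",
    "ReviewSummary",
    "accuracy_after_review",
    "review_curve",
    "random_review_curve",
    "optimal_order",
    "confidence_order",
    "improvement_over_random",
    "review_efficiency",
    "review_summary",
]

#: Below this clip count the random baseline enumerates all orderings.
_EXHAUSTIVE_LIMIT = 7


def _check_clips(accs, sizes):
    accs = np.asarray(accs, dtype=np.float64)
    sizes = np.asarray(sizes, dtype=np.float64)
    if accs.size == 0 or accs.shape != sizes.shape:
        raise ValueError("need matched, non-empty accuracies and sizes")
    if np.any((accs < 0) | (accs > 1)) or np.any(sizes <= 0):
        raise ValueError("accuracies must lie in [0,1] and sizes be positive")
    return accs, sizes


@dataclass
class ReviewCurve:
    """acc(D_k) for k = 0..n under one ordering (or a random expectation)."""

    name: str
    acc_k: np.ndarray  # length n+1
    order: np.ndarray | None = None  # clip indices, review order

    @property
    def n(self) -> int:
        return len(self.acc_k) - 1


def accuracy_after_review(accs, sizes, order, k: int) -> float:
    """Dataset accuracy after reviewing the first ``k`` clips of ``order``."""
    accs, sizes = _check_clips(accs, sizes)
    n = len(accs)
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, {n}], got {k}")
    order = np.asarray(order, dtype=np.int64)
    if sorted(order.tolist()) != list(range(n)):
        raise ValueError("order must be a permutation of all clip indices")
    total = sizes.sum()
    reviewed = order[:k]
    unreviewed = order[k:]
    return float(
        sizes[reviewed].sum() / total
        + (accs[unreviewed] * sizes[unreviewed]).sum() / total
    )


def review_curve(accs, sizes, order, name: str = "ordering") -> ReviewCurve:
    """acc(D_k) at every budget k for one fixed review order."""
    accs, sizes = _check_clips(accs, sizes)
    order = np.asarray(order, dtype=np.int64)
    total = sizes.sum()
    # incremental: reviewing clip i raises dataset accuracy by (1-acc_i)*w_i
    acc0 = float((accs * sizes).sum() / total)
    gains = (1.0 - accs[order]) * sizes[order] / total
    acc_k = np.concatenate([[acc0], acc0 + np.cumsum(gains)])
    acc_k[-1] = 1.0  # exact endpoint
    return ReviewCurve(name=name, acc_k=acc_k, order=order)


def optimal_order(accs, sizes=None) -> np.ndarray:
    """Ascending-true-accuracy review order (ties broken by clip index)."""
    accs = np.asarray(accs, dtype=np.float64)
    return np.lexsort((np.arange(len(accs)), accs))


def confidence_order(confidences) -> np.ndarray:
    """Ascending-confidence review order (ties broken by clip index)."""
    conf = np.asarray(confidences, dtype=np.float64)
    return np.lexsort((np.arange(len(conf)), conf))


def random_review_curve(
    accs, sizes, n_permutations: int = 100, seed: int = 0
) -> ReviewCurve:
    """Expected review curve under a uniformly random ordering.

    Exhaustive over all n! orderings when n < 7; otherwise the Monte-Carlo
    mean over ``n_permutations`` seeded permutations.
    """
    accs, sizes = _check_clips(accs, sizes)
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    n = len(accs)
    if n < _EXHAUSTIVE_LIMIT:
        perms = list(itertools.permutations(range(n)))
        curves = [review_curve(accs, sizes, p).acc_k for p in perms]
    else:
        rng = np.random.default_rng(seed)
        curves = [
            review_curve(accs, sizes, rng.permutation(n)).acc_k
            for _ in range(n_permutations)
        ]
    return ReviewCurve(name="random(expectation)", acc_k=np.mean(curves, axis=0))


def improvement_over_random(curve_method: ReviewCurve, curve_random: ReviewCurve):
    """IOR_k series and its mean: (1/n) · Σ_{k=0..n} IOR_k."""
    if curve_method.n != curve_random.n:
        raise ValueError("curves are on different k grids")
    ior_k = curve_method.acc_k - curve_random.acc_k
    mean_ior = float(ior_k.sum() / curve_method.n)
    return ior_k, mean_ior


def review_efficiency(mean_ior_method: float, mean_ior_opt: float) -> float:
    """Mean-IOR ratio of a candidate ordering to the optimal ordering.

    1 when the candidate's curve matches the optimal one, 0 in expectation
    for a random ordering, negative for worse-than-random orderings.
    Undefined (raises) when the optimal ordering itself brings no
    improvement, i.e. all clips are equally accurate.
    """
    if mean_ior_opt <= 0:
        raise ValueError(
            "review efficiency undefined: optimal ordering has no "
            "improvement over random (all clips equally accurate?)"
        )
    return float(mean_ior_method / mean_ior_opt)


@dataclass
class ReviewSummary:
    """Curves and global measures for one candidate review ordering."""

    curve_candidate: ReviewCurve
    curve_optimal: ReviewCurve
    curve_random: ReviewCurve
    ior_candidate: np.ndarray
    ior_optimal: np.ndarray
    mean_ior_candidate: float
    mean_ior_optimal: float
    efficiency: float


def review_summary(
    accs,
    sizes,
    confidences=None,
    order=None,
    n_permutations: int = 100,
    seed: int = 0,
) -> ReviewSummary:
    """Full review analysis for a confidence-based (or explicit) ordering."""
    accs, sizes = _check_clips(accs, sizes)
    if order is None:
        if confidences is None:
            raise ValueError("provide either confidences or an explicit order")
        order = confidence_order(confidences)
    cand = review_curve(accs, sizes, order, name="candidate")
    opt = review_curve(accs, sizes, optimal_order(accs), name="optimal(accuracy)")
    rand = random_review_curve(accs, sizes, n_permutations=n_permutations, seed=seed)
    ior_c, mean_c = improvement_over_random(cand, rand)
    ior_o, mean_o = improvement_over_random(opt, rand)
    return ReviewSummary(
        curve_candidate=cand,
        curve_optimal=opt,
        curve_random=rand,
        ior_candidate=ior_c,
        ior_optimal=ior_o,
        mean_ior_candidate=mean_c,
        mean_ior_optimal=mean_o,
        efficiency=review_efficiency(mean_c, mean_o),
    )
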