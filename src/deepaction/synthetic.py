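"""Synthetic fixtures: behavior videos, feature processes, and calibrated
or miscalibrated classifiers.

These generators emulate the structure of laboratory behavior datasets —
mutually exclusive behaviors with Markov bout structure, class imbalance,
and behavior-dependent motion — so every pipeline stage is testable without
any external video or pretrained weights.  Feature-level fixtures (Gaussian
class-conditional 512-d features) bypass the CNN for fast unit tests;
video-level fixtures (a moving textured blob) exercise the full
frames→flow→features path.

All randomness flows from one seed through named substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .project import BehaviorSet

__all__ = [
    "BehaviorKernel",
    "SyntheticBehaviorSpec",
    "SyntheticFeatureSpec",
    "substream",
    "generate_label_sequence",
    "generate_video",
    "generate_features",
    "generate_calibrated_logits",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child RNG of a project seed.

    Uses a stable (non-salted) digest of the name so substreams are
    identical across processes and sessions.
    """
    digest = int.from_bytes(name.encode("utf-8").ljust(4, b"\0")[:8], "big")
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(digest % (2**31),))
    return np.random.default_rng(ss)


_rng_for = substream


@dataclass(frozen=True)
class BehaviorKernel:
    """Motion statistics of one behavior: blob velocity and jitter (px/frame)."""

    velocity: tuple[float, float] = (0.0, 0.0)
    jitter: float = 0.0
    blob_sigma: float = 6.0


@dataclass
class SyntheticBehaviorSpec:
    """A synthetic ethogram: behaviors, bout structure, motion, geometry."""

    behavior_set: BehaviorSet
    kernels: dict[str, BehaviorKernel]
    p_stay: dict[str, float] | float = 0.9
    weights: np.ndarray | None = None  # stationary class weights
    fps: float = 10.0
    frame_size: tuple[int, int] = (64, 64)

    def __post_init__(self):
        K = self.behavior_set.K
        if isinstance(self.p_stay, (int, float)):
            self.p_stay = {l: float(self.p_stay) for l in self.behavior_set.labels}
        for l, p in self.p_stay.items():
            if not 0 <= p < 1:
                raise ValueError(f"p_stay[{l!r}] must be in [0, 1)")
        if self.weights is None:
            self.weights = np.full(K, 1.0 / K)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape != (K,) or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("class weights must sum to 1 over K behaviors")
        missing = set(self.behavior_set.labels) - set(self.kernels)
        if missing:
            raise ValueError(f"missing motion kernels for {sorted(missing)}")

    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic Markov matrix: stay with p_stay, else switch to
        other behaviors in proportion to their stationary weights."""
        K = self.behavior_set.K
        T = np.zeros((K, K))
        for i, li in enumerate(self.behavior_set.labels):
            p = self.p_stay[li]
            others = np.delete(self.weights, i)
            T[i, i] = p
            if others.sum() > 0:
                rest = (1.0 - p) * others / others.sum()
                T[i, np.arange(K) != i] = rest
            else:
                T[i, i] = 1.0
        if not np.allclose(T.sum(axis=1), 1.0):
            raise ValueError("transition matrix rows must sum to 1")
        return T


def generate_label_sequence(spec: SyntheticBehaviorSpec, n_frames: int, seed: int) -> np.ndarray:
    """Sample a first-order Markov behavior sequence of ``n_frames`` labels."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    T = spec.transition_matrix()
    rng = _rng_for(seed, "labels")
    K = spec.behavior_set.K
    states = np.empty(n_frames, dtype=np.int64)
    states[0] = rng.choice(K, p=spec.weights)
    for j in range(1, n_frames):
        states[j] = rng.choice(K, p=T[states[j - 1]])
    return spec.behavior_set.to_labels(states)


def generate_video(spec: SyntheticBehaviorSpec, n_frames: int, seed: int):
    """Render a textured blob whose motion follows the active behavior.

    Returns (frames, labels): frames are uint8 grayscale of ``frame_size``;
    the blob moves with the active behavior's velocity (plus jitter),
    bouncing off frame edges, over a static textured background.
    """
    h, w = spec.frame_size
    if h < 64 or w < 64:
        raise ValueError("frame size must be at least 64×64")
    labels = generate_label_sequence(spec, n_frames, seed)
    rng = _rng_for(seed, "video")
    # static mid-contrast textured background so flow is well-constrained
    background = 0.35 + 0.25 * rng.random((h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    pos = np.array([h / 2.0, w / 2.0])
    heading = np.array([1.0, 1.0])  # flips on wall bounces
    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    for j, label in enumerate(labels):
        kern = spec.kernels[label]
        vy, vx = kern.velocity[1], kern.velocity[0]
        step = heading * np.array([vy, vx]) + kern.jitter * rng.standard_normal(2)
        pos = pos + step
        # bounce off edges with a margin, reversing the travel direction
        m = 3 * kern.blob_sigma
        for d, lim in ((0, h), (1, w)):
            if pos[d] < m:
                pos[d] = 2 * m - pos[d]
                heading[d] = -heading[d]
            elif pos[d] > lim - m:
                pos[d] = 2 * (lim - m) - pos[d]
                heading[d] = -heading[d]
        weight = np.exp(
            -((yy - pos[0]) ** 2 + (xx - pos[1]) ** 2) / (2.0 * kern.blob_sigma**2)
        )
        # sinusoidal carrier moving rigidly with the blob gives it internal
        # texture, so dense flow inside the blob is well-constrained
        pattern = 0.5 + 0.45 * np.cos(0.8 * (yy - pos[0])) * np.cos(0.8 * (xx - pos[1]))
        img = np.clip(background * (1.0 - weight) + pattern * weight, 0.0, 1.0)
        frames[j] = np.round(img * 255).astype(np.uint8)
    return frames, labels


@dataclass
class SyntheticFeatureSpec:
    """Class-conditional Gaussian feature process in d dimensions.

    Class means are placed on scaled coordinate axes so every pair of means
    is exactly ``separation × sigma`` apart; features are N(μ_class, σ²I).
    """

    behavior_set: BehaviorSet
    d: int = 512
    sigma: float = 1.0
    separation: float = 6.0  # pairwise mean distance, in units of sigma

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")
        if self.d < self.behavior_set.K:
            raise ValueError("need d >= K to place class means")

    def class_means(self) -> np.ndarray:
        scale = self.separation * self.sigma / np.sqrt(2.0)
        means = np.zeros((self.behavior_set.K, self.d))
        for k in range(self.behavior_set.K):
            means[k, k] = scale
        return means


def generate_features(spec: SyntheticFeatureSpec, labels, seed: int) -> np.ndarray:
    """Draw x_j ~ N(μ_{y_j}, σ²I) for each frame label; shape (n, d)."""
    idx = spec.behavior_set.to_indices(labels)
    rng = _rng_for(seed, "features")
    means = spec.class_means()
    return means[idx] + spec.sigma * rng.standard_normal((len(idx), spec.d))


def generate_calibrated_logits(
    labels,
    behavior_set: BehaviorSet,
    base_accuracy: float = 0.8,
    overconfidence_scale: float = 1.0,
    seed: int = 0,
    confidence_spread: float = 0.1,
):
    """Emit logits from a classifier of known accuracy and calibration.

    For each frame a true posterior is built with mass q on one class
    (q drawn around ``base_accuracy``, always > 1/K so that class is the
    argmax) and the true label is then sampled *from that posterior*, so the
    log-posterior logits are perfectly calibrated by construction.  Returned
    logits are the log-posteriors multiplied by ``overconfidence_scale`` s:
    s = 1 is calibrated (fitted temperature ≈ 1), s > 1 overconfident
    (fitted temperature ≈ s).

    Returns (logits, sampled_true_labels) — the sampled labels replace the
    input labels' identities frame-by-frame while keeping their count.
    """
    K = behavior_set.K
    n = len(np.asarray(labels, dtype=object))
    if not (1.0 / K) < base_accuracy < 1.0:
        raise ValueError(f"base_accuracy must be in (1/K, 1) = ({1/K:.3f}, 1)")
    if overconfidence_scale <= 0:
        raise ValueError("overconfidence_scale must be positive")
    rng = _rng_for(seed, "logits")
    lo = max(base_accuracy - confidence_spread, 1.0 / K + 1e-3)
    hi = min(base_accuracy + confidence_spread, 1.0 - 1e-3)
    # recenter so E[q] = base_accuracy even after clipping at the ends
    if hi - lo > 1e-9:
        center = (lo + hi) / 2.0
        shift = base_accuracy - center
        lo, hi = lo + max(shift, 0.0), hi + min(shift, 0.0)
    q = rng.uniform(lo, hi, size=n)
    top = rng.integers(0, K, size=n)
    posteriors = ((1.0 - q) / (K - 1))[:, None] * np.ones((n, K))
    posteriors[np.arange(n), top] = q
    # sample the "true" labels from the stated posterior => calibration holds
    u = rng.random(n)
    cdf = np.cumsum(posteriors, axis=1)
    y = (u[:, None] > cdf).sum(axis=1)
    logits = overconfidence_scale * np.log(posteriors)
    return logits, behavior_set.to_labels(y)
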