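"""Convolutional feature-extraction backbones.

Features are extracted from the global-average-pooling layer of a
ResNet18-class network: a stack of strided 3×3 convolutions (bias-free, as
in ResNet) ending in 512 channels, spatially averaged to a 512-vector per
frame.  Weights are drawn from a seeded He-normal initialization, so feature
extraction is fully deterministic and needs no weight downloads; the
backbone interface is pluggable, so a pretrained network can be dropped in
where available.

For the temporal ("flow") stream, the first convolution's kernel is tiled
along its input channels so the network accepts stacks of flow images
(3 × stack_size channels) while every other layer is unchanged.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ConvBackbone", "make_flow_backbone", "FEATURE_DIM"]

#: Dimensionality of the extracted per-frame feature vector.
FEATURE_DIM = 512

_DEFAULT_CHANNELS = (32, 64, 128, 256, 512)


def _conv2d(x: np.ndarray, w: np.ndarray, stride: int = 2) -> np.ndarray:
    """Strided 3×3 convolution with 1-px zero padding, channels-last.

    x : (n, H, W, C_in); w : (kh, kw, C_in, C_out) → (n, H', W', C_out).
    """
    kh, kw, c_in, c_out = w.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # n,H,W,C,kh,kw
    win = win[:, ::stride, ::stride]
    n, ho, wo = win.shape[:3]
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * ho * wo, kh * kw * c_in)
    wm = w.transpose(0, 1, 2, 3).reshape(kh * kw * c_in, c_out)
    out = cols @ wm
    return out.reshape(n, ho, wo, c_out)


class ConvBackbone:
    """Seeded random-weight convolutional backbone with 512-d GAP features.

    Parameters
    ----------
    in_channels : input channel count (3 for RGB frames).
    channels : output channels of the successive stride-2 conv layers; the
        last entry fixes the feature dimensionality (512 by default).
    seed : weight-initialization seed; identical seeds give bit-identical
        features.
    """

    def __init__(
        self,
        in_channels: int = 3,
        channels: tuple[int, ...] = _DEFAULT_CHANNELS,
        kernel: int = 3,
        seed: int = 0,
    ):
        self.in_channels = in_channels
        self.channels = tuple(channels)
        self.kernel = kernel
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        c_prev = in_channels
        for c in self.channels:
            fan_in = kernel * kernel * c_prev
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kernel, kernel, c_prev, c))
            self.weights.append(w.astype(np.float32))
            c_prev = c

    @property
    def feature_dim(self) -> int:
        return self.channels[-1]

    def first_layer_response(self, x: np.ndarray) -> np.ndarray:
        """Pre-activation output of the first convolution (for diagnostics)."""
        return _conv2d(self._check(x), self.weights[0])

    def _check(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.shape[-1] != self.in_channels:
            raise ValueError(
                f"backbone expects {self.in_channels} input channels, "
                f"got {x.shape[-1]}"
            )
        return x

    def features(self, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Global-average-pooled features, one row per input frame."""
        x = self._check(x)
        out = np.empty((x.shape[0], self.feature_dim), dtype=np.float32)
        for lo in range(0, x.shape[0], batch_size):
            h = x[lo : lo + batch_size]
            for w in self.weights:
                h = np.maximum(_conv2d(h, w), 0.0)
            out[lo : lo + h.shape[0]] = h.mean(axis=(1, 2))
        return out


def make_flow_backbone(backbone: ConvBackbone, stack_size: int = 11) -> ConvBackbone:
    """Adapt a backbone to stacked flow-image input.

    The first convolution's kernel is replicated ``stack_size`` times along
    its input-channel axis (3 → 3·stack_size channels); all downstream
    weights are shared unchanged with the source backbone.
    """
    if not backbone.weights:
        raise ValueError("backbone has no convolution layers")
    w0 = backbone.weights[0]
    if w0.shape[2] != 3:
        raise ValueError(
            f"unsupported backbone: first convolution takes {w0.shape[2]} "
            "channels, expected 3"
        )
    flow_bb = ConvBackbone.__new__(ConvBackbone)
    flow_bb.in_channels = 3 * stack_size
    flow_bb.channels = backbone.channels
    flow_bb.kernel = backbone.kernel
    flow_bb.seed = backbone.seed
    flow_bb.weights = [np.tile(w0, (1, 1, stack_size, 1))] + backbone.weights[1:]
    return flow_bb
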