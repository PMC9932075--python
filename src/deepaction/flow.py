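"""Dense TV-L1 optical flow and its visual encoding as temporal frames.

Motion between sequential frames is estimated with the TV-L1 algorithm
(total-variation regularization, L1 data term) and rendered to an HSV
"flow image" in which hue encodes motion orientation and brightness motion
magnitude, so that the same CNN feature extractor can be applied to motion
as to appearance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import hsv2rgb, rgb2gray
from skimage.registration import optical_flow_tvl1

__all__ = ["TVL1Params", "compute_tvl1_flow", "flow_to_image", "flow_max_magnitude"]


@dataclass(frozen=True)
class TVL1Params:
    """TV-L1 solver parameters (reference-implementation defaults).

    attachment : weight of the L1 data term (λ);
    tightness : coupling between the flow and the auxiliary field (θ);
    num_warp / num_iter : warps per pyramid level and solver iterations;
    tol : stopping tolerance; prefilter : median-prefilter the images.
    """

    attachment: float = 15.0
    tightness: float = 0.3
    num_warp: int = 5
    num_iter: int = 10
    tol: float = 1e-4
    prefilter: bool = False


def _as_gray(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim == 3:
        frame = rgb2gray(frame)
    if frame.dtype == np.uint8:
        frame = frame.astype(np.float64) / 255.0
    return frame.astype(np.float64)


def compute_tvl1_flow(
    frame_a: np.ndarray, frame_b: np.ndarray, params: TVL1Params | None = None
) -> np.ndarray:
    """Dense TV-L1 optical flow for the motion from ``frame_a`` to ``frame_b``.

    Returns
    -------
    ndarray of shape (H, W, 2)
        Per-pixel displacement ``(dx, dy)`` in pixels/frame: a feature that
        moves right between the two frames has positive dx.
    """
    a, b = _as_gray(frame_a), _as_gray(frame_b)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    p = params or TVL1Params()
    # skimage registers b onto a; its (d_row, d_col) field equals the a→b motion
    v = optical_flow_tvl1(
        a,
        b,
        attachment=p.attachment,
        tightness=p.tightness,
        num_warp=p.num_warp,
        num_iter=p.num_iter,
        tol=p.tol,
        prefilter=p.prefilter,
    )
    flow = np.stack([v[1], v[0]], axis=-1)  # (dx, dy)
    return flow.astype(np.float32)


def flow_max_magnitude(flows, percentile: float = 99.0) -> float:
    """Per-video normalization constant: a high percentile of flow magnitude.

    Using one fixed constant per video (rather than per frame) keeps flow-image
    brightness comparable across frames of the same video.
    """
    mags = [np.hypot(f[..., 0], f[..., 1]).ravel() for f in flows]
    value = float(np.percentile(np.concatenate(mags), percentile))
    return max(value, 1e-6)


def flow_to_image(flow: np.ndarray, max_magnitude: float) -> np.ndarray:
    """Render a flow field as an 8-bit RGB image.

    Hue encodes flow orientation (cyclic color wheel), brightness encodes
    magnitude relative to ``max_magnitude`` (clipped at 1), saturation is
    maximal.  Zero motion maps to black.
    """
    if max_magnitude <= 0:
        raise ValueError("max_magnitude must be positive")
    flow = np.asarray(flow, dtype=np.float64)
    dx, dy = flow[..., 0], flow[..., 1]
    mag = np.hypot(dx, dy)
    angle = np.arctan2(dy, dx)  # (-pi, pi]
    hue = (angle % (2.0 * np.pi)) / (2.0 * np.pi)
    value = np.clip(mag / max_magnitude, 0.0, 1.0)
    hsv = np.stack([hue, np.ones_like(hue), value], axis=-1)
    rgb = hsv2rgb(hsv)
    return np.round(rgb * 255.0).astype(np.uint8)
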