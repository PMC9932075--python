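"""Two-stream feature extraction: preprocessing, flow stacking, concatenation.

Appearance ("spatial") frames and optical-flow ("temporal") frames each pass
through a CNN backbone whose global-average-pooling layer yields one
512-vector per frame.  Temporal frames are stacked with their five
predecessors and five successors (33 channels) so the network sees
short-term motion context.  Per-camera spatial and temporal features are
concatenated (camera-major, spatial before temporal) and reduced back to
512 dimensions by RICA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .backbone import ConvBackbone, FEATURE_DIM

__all__ = [
    "FeatureMatrix",
    "preprocess_frames",
    "build_flow_stacks",
    "extract_stream_features",
    "concat_features",
    "INPUT_SIZE",
    "STACK_SIZE",
]

#: Backbone input width/height in pixels.
INPUT_SIZE = 224
#: Number of flow images stacked per temporal input (must be odd).
STACK_SIZE = 11

# Channel normalization applied after scaling pixels to [0, 1].
_CHANNEL_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
_CHANNEL_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


@dataclass
class FeatureMatrix:
    """Per-frame features for one clip, with provenance metadata."""

    values: np.ndarray  # (n_frames, d)
    stream: str  # spatial | temporal | concat | reduced
    cameras: tuple[str, ...] = ("cam0",)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("feature values must be a 2-D (frames × d) array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def preprocess_frames(frames, size: int = INPUT_SIZE) -> np.ndarray:
    """Resize frames to ``size``×``size`` RGB and normalize channels.

    Accepts uint8 or float images, grayscale or RGB; returns a float32 array
    of shape (n, size, size, 3) scaled to [0, 1] then channel-standardized.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("no frames to preprocess")
    out = np.empty((len(frames), size, size, 3), dtype=np.float32)
    for i, frame in enumerate(frames):
        try:
            f = np.asarray(frame)
            if f.ndim == 2:
                f = np.stack([f] * 3, axis=-1)
            if f.shape[-1] != 3:
                raise ValueError(f"expected 1 or 3 channels, got {f.shape[-1]}")
            if f.dtype == np.uint8:
                f = f.astype(np.float32) / 255.0
            if f.shape[:2] != (size, size):
                f = resize(f, (size, size), anti_aliasing=True, preserve_range=True)
            out[i] = (f - _CHANNEL_MEAN) / _CHANNEL_STD
        except ValueError:
            raise
        except Exception as e:  # unreadable frame
            raise IOError(f"could not preprocess frame {i}: {e}") from e
    return out


def build_flow_stacks(flow_frames: np.ndarray, stack_size: int = STACK_SIZE) -> np.ndarray:
    """Stack each flow frame with its temporal neighbors along channels.

    For frame j the stack holds frames j−h .. j+h (h = stack_size // 2),
    edge-replicating the first/last flow image at clip boundaries.  Output
    shape is (n, H, W, 3·stack_size).
    """
    if stack_size < 1 or stack_size % 2 == 0:
        raise ValueError("stack_size must be odd and >= 1")
    flow_frames = np.asarray(flow_frames)
    if flow_frames.ndim != 4 or flow_frames.shape[0] == 0:
        raise ValueError("flow_frames must be a non-empty (n, H, W, C) array")
    n = flow_frames.shape[0]
    half = stack_size // 2
    idx = np.clip(np.arange(n)[:, None] + np.arange(-half, half + 1)[None, :], 0, n - 1)
    stacks = flow_frames[idx]  # (n, stack, H, W, C)
    n_, s, h, w, c = stacks.shape
    return stacks.transpose(0, 2, 3, 1, 4).reshape(n_, h, w, s * c)


def extract_stream_features(
    inputs: np.ndarray,
    backbone: ConvBackbone,
    stream: str = "spatial",
    cameras: tuple[str, ...] = ("cam0",),
) -> FeatureMatrix:
    """Run preprocessed frames (or flow stacks) through a backbone.

    Returns one feature row per input frame, in input order.
    """
    inputs = np.asarray(inputs, dtype=np.float32)
    if inputs.ndim != 4:
        raise ValueError("inputs must be (n, H, W, C)")
    if inputs.shape[-1] != backbone.in_channels:
        raise ValueError(
            f"backbone expects {backbone.in_channels} channels, "
            f"inputs have {inputs.shape[-1]}"
        )
    values = backbone.features(inputs)
    return FeatureMatrix(values=values, stream=stream, cameras=cameras)


def concat_features(matrices: list[FeatureMatrix]) -> FeatureMatrix:
    """Concatenate per-stream, per-camera features along the feature axis.

    Callers supply matrices in the fixed fusion order (camera-major, spatial
    before temporal); with one camera the result is n×1024, with two n×2048.
    """
    if not matrices:
        raise ValueError("nothing to concatenate")
    n = matrices[0].n_frames
    for m in matrices:
        if m.n_frames != n:
            raise ValueError(
                f"row-count mismatch: {m.n_frames} vs {n} frames"
            )
    values = np.concatenate([m.values for m in matrices], axis=1)
    cameras = tuple(dict.fromkeys(c for m in matrices for c in m.cameras))
    return FeatureMatrix(values=values, stream="concat", cameras=cameras)
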