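"""Extract two-stream CNN features and reduce them with RICA.

A handful of frames pass through the spatial backbone (512-d each) and
stacked flow images through the flow backbone (33 input channels, 512-d
out); the streams are concatenated to 1024-d and reduced back to a compact
spatiotemporal representation by reconstruction ICA.
"""

import numpy as np

from deepaction import (
    ConvBackbone,
    apply_rica,
    build_flow_stacks,
    concat_features,
    extract_stream_features,
    fit_rica,
    make_flow_backbone,
    preprocess_frames,
)

rng = np.random.default_rng(0)
n = 6
raw = rng.integers(0, 256, (n, 120, 160, 3), dtype=np.uint8)
flow_imgs = rng.integers(0, 256, (n, 120, 160, 3), dtype=np.uint8)

frames = preprocess_frames(raw)
print(f"preprocessed frames: {frames.shape}  (224 x 224 RGB)")

backbone = ConvBackbone(seed=0)          # seeded random weights, 512-d GAP
spatial = extract_stream_features(frames, backbone, "spatial")
stacks = build_flow_stacks(preprocess_frames(flow_imgs), stack_size=11)
print(f"flow stacks: {stacks.shape}  (3 channels x 11 stacked flow images)")
temporal = extract_stream_features(stacks, make_flow_backbone(backbone), "temporal")
concat = concat_features([spatial, temporal])
print(f"spatial {spatial.values.shape}, temporal {temporal.values.shape}, "
      f"concatenated {concat.values.shape}")

# RICA demo at reduced scale (the production setting is 1024 -> 512)
X = rng.standard_normal((300, 64))
transform = fit_rica(X, d_out=16, n_iter=100, seed=1)
reduced = apply_rica(transform, X)
print(f"RICA: {X.shape[1]}-d -> {reduced.shape[1]}-d; objective "
      f"{transform.objective_trace[0]:.3f} -> {transform.objective_trace[1]:.3f}")
# The objective (reconstruction error + independence penalty) decreases from
# its random initialization; the transform is a plain linear map.
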