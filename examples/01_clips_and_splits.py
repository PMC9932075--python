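"""Divide a video into clips and simulate selecting a labeled subset.

A 30-minute, 10 fps recording is cut into one-minute clips; 30 % of the
clips are chosen (uniformly, seeded) as the set a user would annotate,
and that labeled set is further split 80/20 into training and validation.
"""

from deepaction import (
    VideoRecord,
    prop_labeled_grid,
    select_labeled_clips,
    split_train_validate,
    split_video_into_clips,
)

video = VideoRecord("session01", n_frames=18_000, fps=10.0)
clips = split_video_into_clips(video, clip_seconds=60.0)
print(f"{video.n_frames} frames at {video.fps} fps -> {len(clips)} clips "
      f"of {clips[0].size} frames")

split = select_labeled_clips(clips, prop_labeled=0.3, seed=42)
train_ids, val_ids = split_train_validate(split.labeled, prop_validate=0.2, seed=42)
print(f"labeled clips: {len(split.labeled)} "
      f"(train {len(train_ids)}, validate {len(val_ids)}); "
      f"unlabeled/test clips: {len(split.unlabeled)}")

grid = prop_labeled_grid()
print(f"learning-curve sweep: {len(grid)} labeled fractions, "
      f"{grid[0]:.2f} .. {grid[-1]:.2f}")
# The counts above partition the 30 clips exactly; the sweep is the grid of
# labeled fractions used to trace accuracy as a function of annotation effort.
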