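"""File-format plumbing: annotation CSVs, frame stores, manifests, features.

Conventions: frame indices are 0-based; bout intervals are half-open
[start_frame, end_frame).  Annotations are stored per-frame internally and
converted to/from bout intervals only at the file boundary.  Spatial and
temporal frames are stored one-archive-per-video (PNG-in-zip), so a video's
frames travel as a single portable file.
"""

from __future__ import annotations

import io as _io
import json
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .metrics import bout_lengths
from .project import BehaviorSet, VideoRecord

__all__ = [
    "write_frame_annotations",
    "read_frame_annotations",
    "write_bout_annotations",
    "read_bout_annotations",
    "frames_to_bouts",
    "bouts_to_frames",
    "write_frame_archive",
    "read_frame_archive",
    "write_manifest",
    "read_manifest",
    "save_features",
    "load_features",
]


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def frames_to_bouts(video_id: str, labels) -> pd.DataFrame:
    """Convert a per-frame label array to half-open bout intervals."""
    table = bout_lengths(labels)
    rows = []
    start = 0
    for label, length in table.bouts:
        rows.append(
            {"video_id": video_id, "start_frame": start,
             "end_frame": start + length, "label": label}
        )
        start += length
    return pd.DataFrame(rows, columns=["video_id", "start_frame", "end_frame", "label"])


def bouts_to_frames(bouts: pd.DataFrame) -> dict[str, np.ndarray]:
    """Expand bout intervals back to per-video per-frame label arrays."""
    out: dict[str, np.ndarray] = {}
    for video_id, grp in bouts.groupby("video_id", sort=False):
        grp = grp.sort_values("start_frame")
        n = int(grp["end_frame"].max())
        labels = np.empty(n, dtype=object)
        for _, row in grp.iterrows():
            labels[int(row.start_frame):int(row.end_frame)] = row.label
        if any(l is None for l in labels):
            raise ValueError(f"bouts for {video_id!r} do not tile all frames")
        out[video_id] = labels
    return out


def write_frame_annotations(path, video_id: str, labels, frames=None,
                            extra: dict | None = None) -> None:
    """Per-frame annotation CSV with columns video_id, frame, label[, ...]."""
    labels = np.asarray(labels, dtype=object)
    frames = np.arange(len(labels)) if frames is None else np.asarray(frames)
    df = pd.DataFrame({"video_id": video_id, "frame": frames, "label": labels})
    for col, values in (extra or {}).items():
        df[col] = values
    df.to_csv(path, index=False)


def read_frame_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"video_id", "frame", "label"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation CSV must have columns {sorted(required)}")
    return df


def write_bout_annotations(path, video_id: str, labels) -> None:
    frames_to_bouts(video_id, labels).to_csv(path, index=False)


def read_bout_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"video_id", "start_frame", "end_frame", "label"}
    if not required <= set(df.columns):
        raise ValueError(f"bout CSV must have columns {sorted(required)}")
    return df


# ---------------------------------------------------------------------------
# frame store (one PNG-in-zip archive per video)
# ---------------------------------------------------------------------------

def write_frame_archive(path, frames) -> None:
    """Write a sequence of images to a single zip archive (PNG entries)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for i, frame in enumerate(frames):
            frame = np.asarray(frame)
            if frame.dtype != np.uint8:
                frame = np.clip(frame, 0, 255).astype(np.uint8)
            buf = _io.BytesIO()
            Image.fromarray(frame).save(buf, format="PNG")
            zf.writestr(f"{i:06d}.png", buf.getvalue())


def read_frame_archive(path) -> np.ndarray:
    """Read all frames of an archive, in index order."""
    with zipfile.ZipFile(path) as zf:
        names = sorted(zf.namelist())
        frames = [np.asarray(Image.open(_io.BytesIO(zf.read(n)))) for n in names]
    return np.stack(frames)


# ---------------------------------------------------------------------------
# manifest / config
# ---------------------------------------------------------------------------

def write_manifest(path, manifest: dict) -> None:
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=True))


def read_manifest(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def video_from_manifest(entry: dict) -> VideoRecord:
    return VideoRecord(
        video_id=entry["video_id"],
        n_frames=int(entry["n_frames"]),
        fps=float(entry["fps"]),
        cameras=int(entry.get("cameras", 1)),
    )


def behavior_set_from_manifest(manifest: dict) -> BehaviorSet:
    return BehaviorSet(
        manifest["behaviors"], background=manifest.get("background")
    )


# ---------------------------------------------------------------------------
# feature containers
# ---------------------------------------------------------------------------

def save_features(path, values: np.ndarray, **metadata) -> None:
    """Persist a per-clip feature matrix with provenance metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, values=values, metadata=json.dumps(metadata))


def load_features(path):
    with np.load(path, allow_pickle=False) as npz:
        values = npz["values"]
        metadata = json.loads(str(npz["metadata"]))
    return values, metadata
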