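"""Project data model: behaviors, videos, clips, and data splitting.

Long videos are divided into fixed-length clips — the atomic unit of
annotation, training, confidence scoring and review.  A fraction
``prop_labeled`` of clips is (simulated as) manually annotated; the labeled
set is further split into training and validation subsets, and the remaining
clips form the unlabeled/test set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

__all__ = [
    "BehaviorSet",
    "VideoRecord",
    "ClipRecord",
    "DataSplit",
    "split_video_into_clips",
    "select_labeled_clips",
    "split_train_validate",
    "kfold_clips",
    "prop_labeled_grid",
    "round_half_away_from_zero",
]

#: Default clip length in seconds (one minute).
DEFAULT_CLIP_SECONDS = 60.0
#: Default fraction of labeled clips held out for validation.
DEFAULT_PROP_VALIDATE = 0.20


def round_half_away_from_zero(x: float) -> int:
    """Round to the nearest integer, with halves going away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class BehaviorSet:
    """An ordered set of mutually exclusive behavior names.

    Parameters
    ----------
    labels : sequence of str
        Unique, non-empty behavior names.  Order defines the class index
        used for logits, confusion matrices and per-class metrics.
    background : str, optional
        At most one label may be flagged as the background/"other" class.
    """

    labels: tuple[str, ...]
    background: str | None = None

    def __init__(self, labels, background=None):
        labels = tuple(labels)
        if not labels:
            raise ValueError("BehaviorSet requires at least one label")
        if len(set(labels)) != len(labels):
            raise ValueError("behavior labels must be unique")
        if background is not None and background not in labels:
            raise ValueError(f"background label {background!r} not in labels")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "background", background)

    @property
    def K(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def to_indices(self, labels) -> np.ndarray:
        """Map an array of label names to integer class indices."""
        lut = {name: i for i, name in enumerate(self.labels)}
        try:
            return np.asarray([lut[l] for l in labels], dtype=np.int64)
        except KeyError as e:
            raise ValueError(f"label {e.args[0]!r} not in behavior set") from None

    def to_labels(self, indices) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)[np.asarray(indices)]


@dataclass(frozen=True)
class VideoRecord:
    """One project video (possibly with several synchronized camera streams)."""

    video_id: str
    n_frames: int
    fps: float
    cameras: int = 1

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("video must contain at least one frame")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.cameras < 1:
            raise ValueError("at least one camera required")


@dataclass
class ClipRecord:
    """A contiguous frame range of one video, with optional per-frame labels.

    Frame ranges are 0-based and half-open: ``[start, end)``.
    """

    clip_id: str
    video_id: str
    start: int
    end: int
    labels: np.ndarray | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid frame range [{self.start}, {self.end})")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != self.size:
                raise ValueError(
                    f"clip {self.clip_id}: {len(self.labels)} labels for "
                    f"{self.size} frames"
                )

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class DataSplit:
    """Labeled/unlabeled (and train/validate) partition of a clip set.

    In simulation mode the unlabeled set doubles as the test set: ground
    truth exists but is hidden from training.
    """

    labeled: list[str]
    unlabeled: list[str]
    train: list[str] = field(default_factory=list)
    validate: list[str] = field(default_factory=list)
    prop_labeled: float = 0.0
    prop_validate: float = 0.0

    @property
    def test(self) -> list[str]:
        return self.unlabeled

    def validate_invariants(self) -> None:
        lab, unlab = set(self.labeled), set(self.unlabeled)
        if lab & unlab:
            raise ValueError("labeled and unlabeled clip sets overlap")
        if self.train or self.validate:
            tr, va = set(self.train), set(self.validate)
            if tr & va:
                raise ValueError("train and validate clip sets overlap")
            if tr | va != lab:
                raise ValueError("train ∪ validate must equal the labeled set")


def split_video_into_clips(
    video: VideoRecord, clip_seconds: float = DEFAULT_CLIP_SECONDS
) -> list[ClipRecord]:
    """Divide a video into consecutive clips of ``clip_seconds`` each.

    Clips tile ``[0, n_frames)`` exactly; the final clip keeps the remainder
    (it may be shorter than the nominal length but never empty).
    """
    if clip_seconds <= 0:
        raise ValueError("clip_seconds must be positive")
    nominal = max(1, round_half_away_from_zero(clip_seconds * video.fps))
    clips = []
    start = 0
    i = 0
    while start < video.n_frames:
        end = min(start + nominal, video.n_frames)
        clips.append(
            ClipRecord(f"{video.video_id}:{i:04d}", video.video_id, start, end)
        )
        start = end
        i += 1
    return clips


def _clip_ids(clips) -> list[str]:
    return [c.clip_id if isinstance(c, ClipRecord) else str(c) for c in clips]


def select_labeled_clips(clips, prop_labeled: float, seed: int) -> DataSplit:
    """Uniformly sample ``prop_labeled`` of clips as the labeled set.

    The labeled count is ``max(1, round_half_away_from_zero(prop * N))``;
    selection is without replacement and reproducible from ``seed``.
    """
    ids = _clip_ids(clips)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 clips to split")
    if not 0 < prop_labeled < 1:
        raise ValueError("prop_labeled must be in (0, 1)")
    n_labeled = max(1, round_half_away_from_zero(prop_labeled * n))
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(n, size=min(n_labeled, n), replace=False).tolist())
    labeled = [ids[i] for i in range(n) if i in chosen]
    unlabeled = [ids[i] for i in range(n) if i not in chosen]
    return DataSplit(labeled=labeled, unlabeled=unlabeled, prop_labeled=prop_labeled)


def split_train_validate(
    labeled, prop_validate: float = DEFAULT_PROP_VALIDATE, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Partition the labeled clip set into train and validation subsets."""
    ids = _clip_ids(labeled)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 labeled clips")
    if not 0 < prop_validate < 1:
        raise ValueError("prop_validate must be in (0, 1)")
    n_val = max(1, round_half_away_from_zero(prop_validate * n))
    n_val = min(n_val, n - 1)  # keep the training set non-empty
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(n, size=n_val, replace=False).tolist())
    validate = [ids[i] for i in range(n) if i in chosen]
    train = [ids[i] for i in range(n) if i not in chosen]
    return train, validate


def kfold_clips(clips, k: int, seed: int) -> list[tuple[list[str], list[str]]]:
    """Shuffled k-fold cross-validation split over clips.

    Folds are near-equal in size (differ by at most one clip) and every clip
    appears in exactly one test fold.
    """
    ids = _clip_ids(clips)
    n = len(ids)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    ids_arr = np.asarray(ids, dtype=object)
    return [
        (list(ids_arr[tr]), list(ids_arr[te])) for tr, te in kf.split(ids_arr)
    ]


def prop_labeled_grid() -> list[float]:
    """The labeled-fraction sweep used for learning curves.

    Steps of 0.02 up to 0.20 (where accuracy changes fastest per unit of
    added training data), then steps of 0.05 up to 0.90 — 24 values total.
    """
    fine = [round(0.02 * i, 2) for i in range(1, 11)]  # 0.02 .. 0.20
    coarse = [round(0.05 * i, 2) for i in range(5, 19)]  # 0.25 .. 0.90
    return fine + coarse
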