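"""Per-frame evaluation: accuracy, precision/recall/F1, confusion, bouts.

All scoring is strictly per-frame.  F1_all is the unweighted mean of the
per-class F1 over *all* K classes in the behavior set, including classes
absent from a given evaluation (their metrics are 0 by convention and
flagged as degenerate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .project import BehaviorSet

__all__ = [
    "ClassMetrics",
    "BoutTable",
    "accuracy",
    "per_class_prf",
    "confusion_matrix",
    "bout_lengths",
    "agreement",
]


def _check_pair(pred, true):
    pred = np.asarray(pred, dtype=object).ravel()
    true = np.asarray(true, dtype=object).ravel()
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape[0]} vs {true.shape[0]}")
    if pred.size == 0:
        raise ValueError("empty label sequences")
    return pred, true


def accuracy(pred, true) -> float:
    """Fraction of frames on which predicted and true labels agree."""
    pred, true = _check_pair(pred, true)
    return float(np.mean(pred == true))


def agreement(annotations_1, annotations_2) -> float:
    """Frame-wise agreement between two independent annotation tracks.

    Computationally identical to accuracy but symmetric in its arguments;
    used as the human inter-observer benchmark.
    """
    return accuracy(annotations_1, annotations_2)


@dataclass
class ClassMetrics:
    """Per-class counts and derived precision/recall/F1 for one behavior."""

    label: str
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    degenerate: bool  # no predicted and/or no true frames for this class


def per_class_prf(pred, true, behavior_set: BehaviorSet):
    """Per-class precision, recall and F1, plus their unweighted mean F1_all.

    precision_k = TP_k/(TP_k+FP_k); recall_k = TP_k/(TP_k+FN_k);
    F1_k = 2·P·R/(P+R).  Zero denominators yield 0 and set the degenerate
    flag, keeping F1_all defined as the plain mean over all K classes.
    """
    pred, true = _check_pair(pred, true)
    for arr, name in ((pred, "pred"), (true, "true")):
        bad = set(arr) - set(behavior_set.labels)
        if bad:
            raise ValueError(f"{name} labels not in behavior set: {sorted(bad)}")
    counts = _sk_confusion(true, pred, labels=list(behavior_set.labels))
    total = counts.sum()
    per_class: dict[str, ClassMetrics] = {}
    f1s = []
    for k, label in enumerate(behavior_set.labels):
        tp = int(counts[k, k])
        fp = int(counts[:, k].sum() - tp)
        fn = int(counts[k, :].sum() - tp)
        tn = int(total - tp - fp - fn)
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = (
            2.0 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        per_class[label] = ClassMetrics(
            label=label, tp=tp, fp=fp, fn=fn, tn=tn,
            precision=precision, recall=recall, f1=f1,
            degenerate=(tp + fp == 0) or (tp + fn == 0),
        )
        f1s.append(f1)
    f1_all = float(np.mean(f1s))
    return per_class, f1_all


def confusion_matrix(pred, true, behavior_set: BehaviorSet, normalize: str = "true-class"):
    """K×K confusion matrix, rows = true class, columns = predicted class.

    With ``normalize="true-class"`` each row with ≥1 true frame sums to 1;
    ``normalize=None`` returns raw counts.
    """
    pred, true = _check_pair(pred, true)
    counts = _sk_confusion(true, pred, labels=list(behavior_set.labels)).astype(float)
    if normalize is None:
        return counts
    if normalize != "true-class":
        raise ValueError(f"unknown normalize mode {normalize!r}")
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(row_sums > 0, counts / row_sums, 0.0)
    return out


@dataclass
class BoutTable:
    """Maximal constant-label runs, in temporal order."""

    bouts: list[tuple[str, int]]  # (label, run length in frames)

    @property
    def n_bouts(self) -> int:
        return len(self.bouts)

    def lengths_by_behavior(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for label, length in self.bouts:
            out.setdefault(label, []).append(length)
        return out

    def total_frames(self) -> int:
        return sum(length for _, length in self.bouts)


def bout_lengths(labels) -> BoutTable:
    """Run-length encode a label sequence into behavior bouts."""
    labels = np.asarray(labels, dtype=object).ravel()
    if labels.size == 0:
        raise ValueError("empty label sequence")
    bouts = []
    current = labels[0]
    run = 1
    for l in labels[1:]:
        if l == current:
            run += 1
        else:
            bouts.append((current, run))
            current, run = l, 1
    bouts.append((current, run))
    return BoutTable(bouts=bouts)
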