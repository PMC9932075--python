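"""Confidence scoring and temperature-scaling calibration.

The frame confidence is the maximum softmax probability ("max softmax
score"), optionally recalibrated by temperature scaling: logits are divided
by a scalar T > 0 fitted to minimize the negative log likelihood on the
validation set (T > 1 softens overconfident probabilities; predicted labels
are unchanged).  Clip confidence is the plain mean of frame confidences;
dataset confidence is the frame-count-weighted mean of clip confidences.
Calibration quality is summarized per clip by the prediction error
PE = conf − acc and its magnitude AE, and across clips by their unweighted
means MSD and MAE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import log_softmax, softmax

__all__ = [
    "TemperatureModel",
    "CalibrationReport",
    "softmax_confidence",
    "fit_temperature",
    "scaled_confidence",
    "clip_confidence",
    "clip_accuracy",
    "dataset_confidence",
    "calibration_errors",
    "negative_log_likelihood",
]

#: Search bounds for the fitted temperature (on log T).
_LOG_T_BOUNDS = (np.log(0.05), np.log(20.0))


def _check_logits(logits) -> np.ndarray:
    logits = np.asarray(logits, dtype=np.float64)
    if logits.ndim != 2 or logits.shape[1] < 2:
        raise ValueError("logits must be (n_frames, K) with K >= 2")
    if not np.all(np.isfinite(logits)):
        raise ValueError("logits must be finite")
    return logits


def softmax_confidence(logits) -> np.ndarray:
    """Per-frame max softmax score, in [1/K, 1]."""
    logits = _check_logits(logits)
    return softmax(logits, axis=1).max(axis=1)


def negative_log_likelihood(logits, label_indices, T: float = 1.0) -> float:
    """Mean cross-entropy of temperature-scaled logits against labels."""
    logits = _check_logits(logits)
    y = np.asarray(label_indices, dtype=np.int64)
    logp = log_softmax(logits / T, axis=1)
    return float(-logp[np.arange(len(y)), y].mean())


@dataclass
class TemperatureModel:
    """A fitted temperature and the NLL at T=1 vs. the fitted T."""

    T: float
    nll_initial: float
    nll_fitted: float


def fit_temperature(logits, label_indices) -> TemperatureModel:
    """Fit T > 0 minimizing validation NLL of softmax(z / T).

    Deterministic 1-D bounded minimization on log T ∈ [log 0.05, log 20].
    """
    logits = _check_logits(logits)
    y = np.asarray(label_indices, dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("temperature fit is degenerate: validation labels "
                         "contain a single class")
    res = minimize_scalar(
        lambda log_t: negative_log_likelihood(logits, y, np.exp(log_t)),
        bounds=_LOG_T_BOUNDS,
        method="bounded",
        options={"xatol": 1e-6},
    )
    T = float(np.exp(res.x))
    nll1 = negative_log_likelihood(logits, y, 1.0)
    nllT = float(res.fun)
    if nllT > nll1:  # bounded search can only improve on T=1 or keep it
        T, nllT = 1.0, nll1
    return TemperatureModel(T=T, nll_initial=nll1, nll_fitted=nllT)


def scaled_confidence(logits, T: float) -> np.ndarray:
    """Max softmax of temperature-divided logits (labels unchanged)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    logits = _check_logits(logits)
    return softmax(logits / T, axis=1).max(axis=1)


def clip_confidence(frame_confidences) -> float:
    """Clip confidence: arithmetic mean of the frame confidences."""
    p = np.asarray(frame_confidences, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty clip")
    return float(p.mean())


def clip_accuracy(pred, true) -> float:
    """Fraction of correct frames in a clip (matches metrics.accuracy)."""
    pred = np.asarray(pred, dtype=object).ravel()
    true = np.asarray(true, dtype=object).ravel()
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError("clip labels missing or mismatched")
    return float(np.mean(pred == true))


def dataset_confidence(clip_values, clip_sizes) -> float:
    """Frame-count-weighted mean of per-clip confidences (or accuracies)."""
    v = np.asarray(clip_values, dtype=np.float64)
    w = np.asarray(clip_sizes, dtype=np.float64)
    if v.size == 0 or v.shape != w.shape:
        raise ValueError("need matched, non-empty clip values and sizes")
    return float(np.sum(v * w / w.sum()))


@dataclass
class CalibrationReport:
    """Per-clip confidence-vs-accuracy errors and their aggregates.

    PE(clip) = conf − acc (positive ⇒ overconfident); AE = |PE|;
    MAE = mean AE; MSD = mean PE (both unweighted over clips).
    """

    conf: np.ndarray
    acc: np.ndarray
    pe: np.ndarray
    ae: np.ndarray
    mae: float
    msd: float
    temperature: float | None = None


def calibration_errors(clip_conf, clip_acc, temperature=None) -> CalibrationReport:
    """Build a calibration report from matched per-clip conf/acc lists."""
    conf = np.asarray(clip_conf, dtype=np.float64)
    acc = np.asarray(clip_acc, dtype=np.float64)
    if conf.shape != acc.shape or conf.size == 0:
        raise ValueError("clip confidence and accuracy lists must match")
    pe = conf - acc
    ae = np.abs(pe)
    return CalibrationReport(
        conf=conf, acc=acc, pe=pe, ae=ae,
        mae=float(ae.mean()), msd=float(pe.mean()),
        temperature=temperature,
    )
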