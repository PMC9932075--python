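"""Reconstruction independent component analysis (RICA).

A linear dimensionality reduction that balances the statistical independence
of the output features against the ability to reconstruct the inputs from
them.  For standardized inputs x (rows of X, N samples) and a mixing matrix
W (d_in × d_out) the objective is

    J(W) = (λ/N) · Σᵢ ‖W Wᵀ xᵢ − xᵢ‖²  +  (1/N) · Σᵢ Σₖ g(wₖᵀ xᵢ),

with the smooth independence surrogate g(z) = log cosh(z).  J is minimized
by L-BFGS from a seeded random initialization; the fitted transform is
purely linear: features_out = features_in_standardized · W.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = ["RicaTransform", "rica_objective", "fit_rica", "apply_rica"]


def _log_cosh(z: np.ndarray) -> np.ndarray:
    # overflow-safe: log cosh z = |z| + log1p(e^{-2|z|}) - log 2
    az = np.abs(z)
    return az + np.log1p(np.exp(-2.0 * az)) - np.log(2.0)


@dataclass
class RicaTransform:
    """A fitted RICA mixing matrix plus the standardization it was fit under."""

    W: np.ndarray  # (d_in, d_out)
    mean: np.ndarray
    std: np.ndarray
    lam: float
    objective_trace: tuple[float, float]  # (initial, final)
    seed: int
    fitted: bool = True

    @property
    def d_in(self) -> int:
        return self.W.shape[0]

    @property
    def d_out(self) -> int:
        return self.W.shape[1]


def rica_objective(W: np.ndarray, X: np.ndarray, lam: float) -> float:
    """Evaluate J(W) on standardized data X (rows are samples)."""
    N = X.shape[0]
    Z = X @ W
    R = Z @ W.T - X
    return float(lam / N * np.sum(R * R) + np.sum(_log_cosh(Z)) / N)


def _objective_and_grad(w_flat, X, lam, d_in, d_out):
    W = w_flat.reshape(d_in, d_out)
    N = X.shape[0]
    Z = X @ W
    R = Z @ W.T - X
    obj = lam / N * np.sum(R * R) + np.sum(_log_cosh(Z)) / N
    grad = (2.0 * lam / N) * (X.T @ R + R.T @ X) @ W + (X.T @ np.tanh(Z)) / N
    return obj, grad.ravel()


def fit_rica(
    X: np.ndarray,
    d_out: int = 512,
    lam: float = 1.0,
    n_iter: int = 200,
    seed: int = 0,
) -> RicaTransform:
    """Fit a RICA transform on pooled training features.

    Inputs are standardized (per-column mean/std) before fitting; the same
    standardization is stored and re-applied at transform time.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples × features)")
    n, d_in = X.shape
    if d_out > d_in:
        raise ValueError(f"d_out={d_out} exceeds input dimension {d_in}")
    if n < d_out:
        raise ValueError(f"need at least d_out={d_out} samples, got {n}")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")

    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std < 1e-12] = 1.0
    Xs = (X - mean) / std

    rng = np.random.default_rng(seed)
    W0 = rng.normal(0.0, 1.0 / np.sqrt(d_in), size=(d_in, d_out))
    obj0 = rica_objective(W0, Xs, lam)

    res = minimize(
        _objective_and_grad,
        W0.ravel(),
        args=(Xs, lam, d_in, d_out),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": n_iter},
    )
    if not np.isfinite(res.fun):
        raise FloatingPointError("RICA objective became non-finite")
    W = res.x.reshape(d_in, d_out)
    return RicaTransform(
        W=W, mean=mean, std=std, lam=lam,
        objective_trace=(obj0, float(res.fun)), seed=seed,
    )


def apply_rica(transform: RicaTransform, X: np.ndarray) -> np.ndarray:
    """Project features through a fitted transform: (X standardized) · W."""
    if not transform.fitted:
        raise ValueError("transform is not fitted")
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != transform.d_in:
        raise ValueError(
            f"X must have {transform.d_in} columns, got {X.shape}"
        )
    Xs = (X - transform.mean) / transform.std
    return Xs @ transform.W
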