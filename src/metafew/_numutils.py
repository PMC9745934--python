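"""Shared numerical helpers: finite-difference Hessians and t intervals."""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "numeric_hessian",
    "t_confidence_interval",
    "safe_inverse_information",
    "covariance_with_active_bounds",
]


def numeric_hessian(f, x, eps: float = 1e-3) -> np.ndarray:
    """Central finite-difference Hessian of a scalar function at x.

    Step is scaled per coordinate by max(1, |x_i|) so the same relative
    resolution is used for intercepts and variance-transform parameters.
    The default step favours noise robustness over truncation error: the
    log likelihoods this is applied to are close to quadratic at the 1e-3
    scale, while their evaluation noise (log-gamma cancellation, inner
    quadrature) can reach 1e-9.
    """
    x = np.asarray(x, dtype=float)
    p = x.size
    h = eps * np.maximum(1.0, np.abs(x))
    hess = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                fpp = f(x + 2 * ei)
                fp = f(x + ei)
                fm = f(x - ei)
                fmm = f(x - 2 * ei)
                hess[i, i] = (-fpp + 16 * fp - 30 * f(x) + 16 * fm - fmm) / (12 * h[i] ** 2)
            else:
                fpp = f(x + ei + ej)
                fpm = f(x + ei - ej)
                fmp = f(x - ei + ej)
                fmm = f(x - ei - ej)
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return hess


def safe_inverse_information(hess: np.ndarray) -> np.ndarray | None:
    """Invert an observed information matrix; None unless positive definite."""
    hess = np.asarray(hess, dtype=float)
    if not np.all(np.isfinite(hess)):
        return None
    try:
        chol = np.linalg.cholesky(hess)
    except np.linalg.LinAlgError:
        return None
    inv_chol = np.linalg.inv(chol)
    return inv_chol.T @ inv_chol


def numeric_hessian_from_grad(grad, x, eps: float = 1e-5) -> np.ndarray:
    """Central finite-difference Hessian from an analytic gradient.

    One difference of an exact gradient is far better conditioned than two
    differences of the function, so the step can be small.
    """
    x = np.asarray(x, dtype=float)
    p = x.size
    h = eps * np.maximum(1.0, np.abs(x))
    hess = np.empty((p, p))
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        hess[:, i] = (grad(x + ei) - grad(x - ei)) / (2 * h[i])
    return 0.5 * (hess + hess.T)


def covariance_with_active_bounds(
    hess: np.ndarray,
    x: np.ndarray,
    bounds,
    atol: float = 1e-6,
    force: np.ndarray | None = None,
) -> tuple[np.ndarray | None, np.ndarray]:
    """Invert an observed information matrix, profiling out active bounds.

    Parameters sitting on a box bound (typically a variance-component
    transform at its floor, where the likelihood is flat) are dropped and
    the remaining block inverted; their covariance rows are zero.  ``force``
    marks parameters to profile out regardless of position (e.g. intercepts
    of studies that carry no information in the boundary limit).  Returns
    (covariance or None, at_bound mask).
    """
    x = np.asarray(x, dtype=float)
    p = x.size
    at_bound = np.zeros(p, dtype=bool)
    if force is not None:
        at_bound |= np.asarray(force, dtype=bool)
    if bounds is not None:
        for i, (lo, hi) in enumerate(bounds):
            if lo is not None and x[i] - lo <= atol:
                at_bound[i] = True
            if hi is not None and hi - x[i] <= atol:
                at_bound[i] = True
    free = ~at_bound
    if not free.any():
        return None, at_bound
    sub = hess[np.ix_(free, free)]
    inv = safe_inverse_information(sub)
    if inv is None:
        return None, at_bound
    cov = np.zeros_like(np.asarray(hess, dtype=float))
    cov[np.ix_(free, free)] = inv
    return cov, at_bound


def t_confidence_interval(est: float, se: float, df: float) -> tuple[float, float]:
    """Two-sided 95% interval est +/- t_{df,0.975} * se."""
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if se < 0:
        raise ValueError("se must be non-negative")
    q = stats.t.ppf(0.975, df)
    return est - q * se, est + q * se
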