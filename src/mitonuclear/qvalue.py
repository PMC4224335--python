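"""Storey false-discovery-rate q-values.

pi0, the proportion of true null hypotheses, is estimated from the
excess of large p-values: pi0_hat(lambda) = #{p > lambda} / (m (1 -
lambda)) over a grid of lambda thresholds.  Two published estimators
are provided: the *smoother* (fit a cubic smoothing spline with 3
effective degrees of freedom to pi0_hat(lambda) and read it off at the
largest lambda) and the *bootstrap* (pick the lambda minimising the
bootstrap-estimated MSE of pi0_hat against the plug-in minimum).  Given
pi0, q-values follow the monotone transform q(i) = min_{j >= i} pi0 *
p(j) * m / j over the sorted p-values; at pi0 = 1 this reduces to
Benjamini-Hochberg adjusted p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline

__all__ = [
    "DEFAULT_LAMBDA_GRID",
    "QValueSet",
    "pi0_raw",
    "pi0_smoother",
    "pi0_bootstrap",
    "qvalues",
    "storey_qvalues",
]

logger = logging.getLogger(__name__)

#: lambda = 0.00, 0.05, ..., 0.90 — the grid of the classic QVALUE package.
DEFAULT_LAMBDA_GRID = np.round(np.arange(0.0, 0.91, 0.05), 2)

_SMALL_M_WARN = 100  # below this many p-values pi0 estimation is unstable


@dataclass(frozen=True)
class QValueSet:
    """p-values with their pi0 estimate and q-values (input order)."""

    pvalues: np.ndarray
    pi0: float
    pi0_method: str
    qvalues: np.ndarray


def _check_pvals(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p-values must be a non-empty 1-D array")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return p


def _check_grid(lambda_grid) -> np.ndarray:
    lam = np.asarray(lambda_grid, dtype=float)
    if lam.ndim != 1 or lam.size == 0:
        raise ValueError("lambda grid must be a non-empty 1-D array")
    if (np.diff(lam) <= 0).any():
        raise ValueError("lambda grid must be strictly increasing")
    if lam[0] < 0 or lam[-1] >= 1:
        raise ValueError("lambda grid must lie within [0, 1)")
    return lam


def pi0_raw(pvals, lambda_grid=DEFAULT_LAMBDA_GRID) -> np.ndarray:
    """Raw pi0_hat(lambda) = #{p > lambda} / (m (1 - lambda)) per grid point."""
    p = _check_pvals(pvals)
    lam = _check_grid(lambda_grid)
    m = p.size
    return np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])


def _spline_with_df(x: np.ndarray, y: np.ndarray, target_df: float) -> np.ndarray:
    """Cubic smoothing spline fit with the penalty tuned to a target
    effective df (trace of the smoother matrix); returns fitted values."""

    def trace_for(lam_penalty: float) -> float:
        tr = 0.0
        for i in range(x.size):
            e = np.zeros_like(y)
            e[i] = 1.0
            tr += make_smoothing_spline(x, e, lam=lam_penalty)(x[i])
        return tr

    lo, hi = 1e-9, 1e9
    # bisect in log-penalty space: trace decreases as the penalty grows
    for _ in range(60):
        mid = np.sqrt(lo * hi)
        if trace_for(mid) > target_df:
            lo = mid
        else:
            hi = mid
    lam_penalty = np.sqrt(lo * hi)
    return make_smoothing_spline(x, y, lam=lam_penalty)(x)


def pi0_smoother(pvals, lambda_grid=DEFAULT_LAMBDA_GRID) -> float:
    """Smoother-method pi0: spline-smooth pi0_hat(lambda), read at max lambda."""
    p = _check_pvals(pvals)
    if p.size < 2:
        raise ValueError("need at least 2 p-values")
    lam = _check_grid(lambda_grid)
    raw = pi0_raw(p, lam)
    if p.size < _SMALL_M_WARN:
        logger.warning(
            "pi0 estimation from only %d p-values is unstable; "
            "consider supplying a fixed pi0",
            p.size,
        )
    if lam.size < 4:
        pi0 = raw[-1]
    else:
        pi0 = _spline_with_df(lam, raw, target_df=3.0)[-1]
    return float(np.clip(pi0, np.finfo(float).tiny, 1.0))


def pi0_bootstrap(
    pvals, lambda_grid=DEFAULT_LAMBDA_GRID, B: int = 100, seed=None
) -> float:
    """Bootstrap-method pi0: choose the lambda minimising the bootstrap MSE
    of pi0_hat(lambda) around the plug-in minimum over the grid."""
    p = _check_pvals(pvals)
    if p.size < 2:
        raise ValueError("need at least 2 p-values")
    lam = _check_grid(lambda_grid)
    if B < 1:
        raise ValueError("B must be >= 1")
    raw = pi0_raw(p, lam)
    if lam.size == 1:
        return float(np.clip(raw[0], np.finfo(float).tiny, 1.0))
    target = raw.min()
    rng = np.random.default_rng(seed)
    m = p.size
    mse = np.zeros(lam.size)
    for _ in range(B):
        pb = rng.choice(p, size=m, replace=True)
        rb = np.array([(pb > l).sum() / (m * (1.0 - l)) for l in lam])
        mse += (rb - target) ** 2
    best = int(np.argmin(mse))
    return float(np.clip(raw[best], np.finfo(float).tiny, 1.0))


def qvalues(pvals, pi0: float = 1.0) -> np.ndarray:
    """Monotone Storey q-values at a given pi0, returned in input order.

    Sorted ascending, raw_i = pi0 * p_(i) * m / i; the q-value is the
    running minimum from the largest rank down, so tied p-values share
    the q of their largest rank.  pi0 = 1 gives Benjamini-Hochberg.
    """
    p = _check_pvals(pvals)
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    raw = pi0 * p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q = np.empty(m)
    q[order] = q_sorted
    return np.minimum(q, 1.0)


def storey_qvalues(
    pvals,
    pi0: float | None = None,
    method: str = "smoother",
    lambda_grid=DEFAULT_LAMBDA_GRID,
    B: int = 100,
    seed=None,
) -> QValueSet:
    """Estimate pi0 (unless fixed) and compute q-values in one call."""
    p = _check_pvals(pvals)
    if pi0 is not None:
        est, tag = float(pi0), "fixed"
    elif method == "smoother":
        est, tag = pi0_smoother(p, lambda_grid), "smoother"
    elif method == "bootstrap":
        est, tag = pi0_bootstrap(p, lambda_grid, B=B, seed=seed), "bootstrap"
    else:
        raise ValueError(f"unknown pi0 method {method!r}")
    return QValueSet(pvalues=p, pi0=est, pi0_method=tag, qvalues=qvalues(p, est))
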