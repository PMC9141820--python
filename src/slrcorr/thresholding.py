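"""Proportional hard-thresholding of correlation matrices.

The threshold h(alpha) is the empirical alpha-quantile (lower order
statistic) of the off-diagonal correlations, so alpha directly controls
the proportion of entries retained: the mask keeps r_ij >= h(alpha),
roughly the top (1 - alpha) fraction.

Thresholding is one-sided on signed correlations: negative entries are
never retained. The diagonal is excluded from the quantile pool and is
always kept in the mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mm import FitResult, fit_multistart

__all__ = [
    "ThresholdSpec",
    "percentile_threshold",
    "build_mask",
    "sparse_corr",
    "sparse_lowrank_corr",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """A percentage point alpha and the realized threshold value h(alpha)."""

    alpha: float
    h: float


def _check_corr(R) -> np.ndarray:
    R = np.asarray(R, dtype=np.float64)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be a square matrix")
    return R


def percentile_threshold(R, alpha: float) -> ThresholdSpec:
    """h(alpha): the alpha-quantile of the strict upper triangle of R.

    Lower-order-statistic (type-1) convention: with the m = p(p-1)/2
    off-diagonal values sorted ascending, h is the ceil(alpha * m)-th
    value (the minimum at alpha = 0, the maximum at alpha = 1). Signed
    values are used, not absolute values.
    """
    R = _check_corr(R)
    p = R.shape[0]
    if p < 2:
        raise ValueError("need p >= 2 for off-diagonal entries")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    vals = np.sort(R[np.triu_indices(p, k=1)])
    m = len(vals)
    k = max(int(np.ceil(alpha * m)), 1)
    return ThresholdSpec(alpha=float(alpha), h=float(vals[k - 1]))


def build_mask(R, h: float) -> np.ndarray:
    """Binary mask W with w_ij = 1 iff r_ij >= h (i != j); diagonal 1.

    The comparison is on signed correlations — a large negative entry is
    masked out regardless of |r_ij|.
    """
    R = _check_corr(R)
    W = R >= h
    np.fill_diagonal(W, True)
    return W


def sparse_corr(R, h: float) -> np.ndarray:
    """Hard-thresholded correlation matrix W (.) R (entries below h zeroed)."""
    R = _check_corr(R)
    return np.where(build_mask(R, h), R, 0.0)


def sparse_lowrank_corr(
    R,
    h: float,
    d: int,
    *,
    n_starts: int = 50,
    eps: float = 1e-6,
    max_iter: int = 1000,
    random_state=None,
) -> tuple[np.ndarray, FitResult]:
    """Sparse low-rank estimate W (.) Y Y^T at threshold h and rank d.

    The mask is built from the full-resolution R (not from a low-rank
    approximation of it); Y minimizes the masked loss via multistart MM.
    Entries where the mask is 0 are exactly 0; the diagonal is exactly 1.
    """
    R = _check_corr(R)
    W = build_mask(R, h)
    res = fit_multistart(
        R, W, d, n_starts=n_starts, eps=eps, max_iter=max_iter, random_state=random_state
    )
    est = np.where(W, res.Y @ res.Y.T, 0.0)
    np.fill_diagonal(est, 1.0)
    return est, res
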