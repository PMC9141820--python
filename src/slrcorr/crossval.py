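"""Threshold selection by repeated random-split cross-validation.

For each candidate percentage point alpha and each of K random splits of
the data into a fitting part (n1 rows) and a holdout part (n2 rows), the
loss is the squared Frobenius distance between a thresholded estimate
built from the fitting part's correlation matrix and the holdout
correlation matrix. The split sizes follow the hard-thresholding
literature: n2 = floor(n / log n) (natural log), n1 = n - n2.

Two CV functions are provided:

* rank-aware ("proposed"): the estimate inside the loss is the masked
  rank-d MM fit W (.) Y Y^T, so the chosen threshold accounts for the
  rank constraint of the final estimator;
* tandem: the estimate is the masked full-rank matrix W (.) R1 — the
  classical thresholding CV, with rank handled only afterwards.

The rank-aware loss grows as the rank shrinks, which pushes the argmin
toward larger alpha, i.e. sparser estimates, than the tandem CV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .thresholding import build_mask, percentile_threshold, sparse_lowrank_corr, sparse_corr
from .mm import FitResult, fit_multistart

__all__ = [
    "CVResult",
    "split_sizes",
    "split_data",
    "cv_proposed",
    "cv_tandem",
    "estimate_proposed",
    "estimate_tandem",
]

_MAX_SPLIT_RETRIES = 20


@dataclass
class CVResult:
    """Per-alpha CV losses and the selected threshold.

    ``chosen_h`` is the realized threshold at ``chosen_alpha`` on the
    full-data correlation matrix (the value the final refit uses);
    ``fold_losses`` has shape (K, len(alpha_grid)).
    """

    alpha_grid: np.ndarray
    cv_values: np.ndarray
    fold_losses: np.ndarray
    chosen_alpha: float
    chosen_h: float
    K: int
    d: int | None = None


def split_sizes(n: int) -> tuple[int, int]:
    """(n1, n2) with n2 = floor(n / ln n) and n1 = n - n2."""
    if n < 4:
        raise ValueError("need n >= 4 for a nonempty holdout")
    n2 = int(np.floor(n / np.log(n)))
    return n - n2, n2


def split_data(X, seed=None):
    """Random partition of the rows of X into (n1 x p, n2 x p) parts."""
    X = np.asarray(X, dtype=np.float64)
    n1, _ = split_sizes(X.shape[0])
    rng = np.random.default_rng(seed)
    perm = rng.permutation(X.shape[0])
    return X[perm[:n1]], X[perm[n1:]]


def _corr(X) -> np.ndarray:
    R = np.corrcoef(X, rowvar=False)
    R = 0.5 * (R + R.T)  # corrcoef is symmetric only up to rounding
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def _has_constant_column(X) -> bool:
    return bool(np.any(np.ptp(X, axis=0) == 0.0))


def _draw_split_corrs(X, rng):
    """Split and correlate, redrawing if a part has a constant column."""
    for _ in range(_MAX_SPLIT_RETRIES):
        X1, X2 = split_data(X, rng)
        if _has_constant_column(X1) or _has_constant_column(X2):
            continue
        return _corr(X1), _corr(X2)
    raise ValueError(
        "could not draw a split without constant columns after "
        f"{_MAX_SPLIT_RETRIES} attempts"
    )


def _run_cv(
    X,
    alpha_grid: Sequence[float],
    *,
    d: int | None,
    K: int,
    n_starts: int,
    eps: float,
    max_iter: int,
    seed,
    common_splits: bool,
) -> CVResult:
    X = np.asarray(X, dtype=np.float64)
    alpha_grid = np.asarray(sorted(float(a) for a in alpha_grid))
    if alpha_grid.size == 0:
        raise ValueError("alpha_grid must be nonempty")
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    fold_losses = np.empty((K, alpha_grid.size))
    shared = [_draw_split_corrs(X, rng) for _ in range(K)] if common_splits else None
    for ai, alpha in enumerate(alpha_grid):
        for k in range(K):
            R1, R2 = shared[k] if common_splits else _draw_split_corrs(X, rng)
            h = percentile_threshold(R1, alpha).h
            if d is None:
                est = sparse_corr(R1, h)
            else:
                est, _ = sparse_lowrank_corr(
                    R1, h, d, n_starts=n_starts, eps=eps, max_iter=max_iter, random_state=rng
                )
            fold_losses[k, ai] = np.sum((est - R2) ** 2)
    cv_values = fold_losses.mean(axis=0)
    # Tie-break toward the largest alpha (the sparser estimate).
    best = np.flatnonzero(cv_values == cv_values.min())[-1]
    chosen_alpha = float(alpha_grid[best])
    chosen_h = percentile_threshold(_corr(X), chosen_alpha).h
    return CVResult(
        alpha_grid=alpha_grid,
        cv_values=cv_values,
        fold_losses=fold_losses,
        chosen_alpha=chosen_alpha,
        chosen_h=chosen_h,
        K=K,
        d=d,
    )


def cv_proposed(
    X,
    alpha_grid,
    d: int,
    K: int = 5,
    *,
    n_starts: int = 50,
    eps: float = 1e-6,
    max_iter: int = 1000,
    seed=None,
    common_splits: bool = False,
) -> CVResult:
    """Rank-aware CV: loss || W (.) Y Y^T - R2 ||_F^2 with Y fit by MM at rank d."""
    return _run_cv(
        X,
        alpha_grid,
        d=int(d),
        K=K,
        n_starts=n_starts,
        eps=eps,
        max_iter=max_iter,
        seed=seed,
        common_splits=common_splits,
    )


def cv_tandem(
    X,
    alpha_grid,
    K: int = 5,
    *,
    seed=None,
    common_splits: bool = False,
) -> CVResult:
    """Rank-ignoring CV: loss || W (.) R1 - R2 ||_F^2 (no MM fit inside)."""
    return _run_cv(
        X,
        alpha_grid,
        d=None,
        K=K,
        n_starts=1,
        eps=1e-6,
        max_iter=1,
        seed=seed,
        common_splits=common_splits,
    )


def _final_fit(X, cv_result, d, n_starts, eps, max_iter, seed):
    R = _corr(np.asarray(X, dtype=np.float64))
    est, fitres = sparse_lowrank_corr(
        R,
        cv_result.chosen_h,
        d,
        n_starts=n_starts,
        eps=eps,
        max_iter=max_iter,
        random_state=seed,
    )
    return est, fitres


def estimate_proposed(
    X,
    alpha_grid,
    d: int,
    K: int = 5,
    *,
    n_starts: int = 50,
    cv_n_starts: int | None = None,
    eps: float = 1e-6,
    max_iter: int = 1000,
    seed=None,
    common_splits: bool = False,
) -> tuple[np.ndarray, CVResult]:
    """Rank-aware threshold selection followed by a full-data refit.

    Runs :func:`cv_proposed` (with ``cv_n_starts`` random starts per
    inner fit, defaulting to ``n_starts``), then rebuilds the mask on the
    full-data correlation matrix at the chosen threshold and refits the
    rank-d factor by multistart MM.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_cv, s_fit = ss.spawn(2)
    cvres = cv_proposed(
        X,
        alpha_grid,
        d,
        K,
        n_starts=n_starts if cv_n_starts is None else cv_n_starts,
        eps=eps,
        max_iter=max_iter,
        seed=s_cv,
        common_splits=common_splits,
    )
    est, _ = _final_fit(X, cvres, d, n_starts, eps, max_iter, s_fit)
    return est, cvres


def estimate_tandem(
    X,
    alpha_grid,
    d: int,
    K: int = 5,
    *,
    n_starts: int = 50,
    eps: float = 1e-6,
    max_iter: int = 1000,
    seed=None,
    common_splits: bool = False,
) -> tuple[np.ndarray, CVResult]:
    """Tandem baseline: threshold by :func:`cv_tandem`, then rank-d MM refit."""
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_cv, s_fit = ss.spawn(2)
    cvres = cv_tandem(X, alpha_grid, K, seed=s_cv, common_splits=common_splits)
    est, _ = _final_fit(X, cvres, d, n_starts, eps, max_iter, s_fit)
    return est, cvres
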