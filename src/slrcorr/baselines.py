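"""Comparison estimators: sample correlation, hard-thresholded correlation
(threshold chosen by the tandem CV), and a converter for externally
estimated precision matrices (e.g. from a graphical-lasso fit)."""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .crossval import CVResult, cv_tandem
from .thresholding import sparse_corr

__all__ = ["sample_correlation", "estimate_jiang_modified", "corr_from_precision"]


def sample_correlation(X) -> np.ndarray:
    """Pearson correlation matrix of the columns of X (unit diagonal)."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be an n x p matrix with n >= 2")
    if np.any(np.ptp(X, axis=0) == 0.0):
        raise ValueError("X has a constant column; correlation undefined")
    R = np.corrcoef(X, rowvar=False)
    R = 0.5 * (R + R.T)  # enforce exact symmetry (corrcoef rounds asymmetrically)
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def estimate_jiang_modified(
    X,
    alpha_grid,
    K: int = 5,
    *,
    seed=None,
    common_splits: bool = False,
) -> tuple[np.ndarray, CVResult]:
    """Sparse correlation without rank reduction.

    The threshold is selected by the tandem CV; the estimate is the
    hard-thresholded full-data sample correlation W (.) R. One-sided
    thresholding (entries below h zeroed, negative entries never kept).
    """
    cvres = cv_tandem(X, alpha_grid, K, seed=seed, common_splits=common_splits)
    est = sparse_corr(sample_correlation(X), cvres.chosen_h)
    return est, cvres


def corr_from_precision(P) -> np.ndarray:
    """Correlation matrix implied by a precision (inverse covariance) matrix.

    Inverts the symmetric positive-definite input and rescales the
    resulting covariance to unit diagonal. Intended for evaluating
    precision matrices produced by external sparse inverse-covariance
    fits, whose implied correlation matrix is generally dense.
    """
    P = np.asarray(P, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("precision matrix must be square")
    if not np.allclose(P, P.T, atol=1e-10):
        raise ValueError("precision matrix must be symmetric")
    try:
        L = linalg.cholesky(P, lower=True)
    except linalg.LinAlgError as err:
        raise ValueError("precision matrix must be positive definite") from err
    S = linalg.cho_solve((L, True), np.eye(P.shape[0]))
    s = np.sqrt(np.diag(S))
    R = S / np.outer(s, s)
    R = 0.5 * (R + R.T)
    np.fill_diagonal(R, 1.0)
    return R
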