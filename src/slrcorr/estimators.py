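"""Scikit-learn style estimators.

:class:`LowRankCorrelationMM` fits the masked unit-diagonal low-rank
approximation to a *correlation matrix* input; the two sparse estimators
consume a raw data matrix (n samples x p variables), select a
proportional hard threshold by cross-validation and expose the final
sparse correlation estimate as ``correlation_``. All follow the sklearn
parameter/attribute conventions and work with ``clone`` and
``get_params``/``set_params``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import crossval
from .baselines import estimate_jiang_modified, sample_correlation
from .mm import fit_multistart
from .thresholding import build_mask, percentile_threshold

__all__ = [
    "LowRankCorrelationMM",
    "SparseLowRankCorrelation",
    "ThresholdedCorrelation",
]

# Candidate percentage points used in the banded/autoregressive
# simulation settings; a sensible default for p ~ 100 problems.
DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.66, 0.8601, 0.02), 2))


class LowRankCorrelationMM(BaseEstimator):
    """Masked low-rank correlation approximation by multistart MM descent.

    Minimizes ``||R - W (.) Y Y^T||_F^2`` over p x d factors Y with
    unit-norm rows, for a fixed binary mask W (all ones by default).

    Parameters
    ----------
    rank : target rank d of the factor.
    n_starts : number of random initializations; the best final
        objective wins.
    eps : per-sweep absolute objective-decrease stopping threshold.
    max_iter : sweep cap per start.
    random_state : seed for the initialization stream.

    Attributes
    ----------
    factor_ : (p, d) fitted factor with unit-norm rows.
    correlation_ : ``W (.) factor_ @ factor_.T`` with unit diagonal.
    objective_ : best final objective value.
    objective_trace_ : non-increasing trace of the winning run.
    n_iter_, converged_ : sweep count / convergence flag of that run.
    """

    def __init__(self, rank=2, n_starts=50, eps=1e-6, max_iter=1000, random_state=None):
        self.rank = rank
        self.n_starts = n_starts
        self.eps = eps
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, R, y=None, mask=None):
        R = np.asarray(R, dtype=np.float64)
        W = np.ones_like(R, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
        res = fit_multistart(
            R,
            W,
            self.rank,
            n_starts=self.n_starts,
            eps=self.eps,
            max_iter=self.max_iter,
            random_state=self.random_state,
        )
        self.factor_ = res.Y
        self.objective_trace_ = res.objective_trace
        self.objective_ = res.objective
        self.n_iter_ = res.n_iter
        self.converged_ = res.converged
        est = np.where(W, res.Y @ res.Y.T, 0.0)
        np.fill_diagonal(est, 1.0)
        self.correlation_ = est
        return self


class SparseLowRankCorrelation(BaseEstimator):
    """Sparse low-rank correlation estimator with CV-tuned threshold.

    Fit on an (n, p) data matrix: a proportional threshold h(alpha) is
    selected over ``alpha_grid`` by repeated-split cross-validation, the
    binary mask is rebuilt from the full-data sample correlation at the
    chosen threshold, and the rank-``rank`` factor is refit by multistart
    MM. ``cv="proposed"`` uses the rank-aware CV loss (the MM fit runs
    inside every fold); ``cv="tandem"`` uses the rank-free thresholding
    loss and applies the rank only in the final refit.

    Attributes
    ----------
    correlation_ : (p, p) sparse low-rank estimate (exact zeros off the
        mask support, unit diagonal).
    sample_correlation_, mask_, factor_ : ingredients of the estimate.
    alpha_, threshold_ : selected percentage point and realized h.
    cv_result_ : :class:`slrcorr.crossval.CVResult` with per-fold losses.
    """

    def __init__(
        self,
        rank=2,
        alpha_grid=DEFAULT_ALPHA_GRID,
        cv="proposed",
        K=5,
        n_starts=50,
        cv_n_starts=None,
        eps=1e-6,
        max_iter=1000,
        common_splits=False,
        random_state=None,
    ):
        self.rank = rank
        self.alpha_grid = alpha_grid
        self.cv = cv
        self.K = K
        self.n_starts = n_starts
        self.cv_n_starts = cv_n_starts
        self.eps = eps
        self.max_iter = max_iter
        self.common_splits = common_splits
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        kwargs = dict(
            n_starts=self.n_starts,
            eps=self.eps,
            max_iter=self.max_iter,
            seed=self.random_state,
            common_splits=self.common_splits,
        )
        if self.cv == "proposed":
            est, cvres = crossval.estimate_proposed(
                X, self.alpha_grid, self.rank, self.K, cv_n_starts=self.cv_n_starts, **kwargs
            )
        elif self.cv == "tandem":
            est, cvres = crossval.estimate_tandem(X, self.alpha_grid, self.rank, self.K, **kwargs)
        else:
            raise ValueError(f"cv must be 'proposed' or 'tandem', got {self.cv!r}")
        self.correlation_ = est
        self.cv_result_ = cvres
        self.alpha_ = cvres.chosen_alpha
        self.threshold_ = cvres.chosen_h
        self.sample_correlation_ = sample_correlation(X)
        self.mask_ = build_mask(self.sample_correlation_, self.threshold_)
        return self


class ThresholdedCorrelation(BaseEstimator):
    """Hard-thresholded sample correlation, threshold tuned by tandem CV.

    No rank reduction: the estimate is ``W (.) R`` on the full-data
    sample correlation. This is the classical proportional-thresholding
    estimator (one-sided: negative correlations are never retained).
    """

    def __init__(self, alpha_grid=DEFAULT_ALPHA_GRID, K=5, common_splits=False, random_state=None):
        self.alpha_grid = alpha_grid
        self.K = K
        self.common_splits = common_splits
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        est, cvres = estimate_jiang_modified(
            X,
            self.alpha_grid,
            self.K,
            seed=self.random_state,
            common_splits=self.common_splits,
        )
        self.correlation_ = est
        self.cv_result_ = cvres
        self.alpha_ = cvres.chosen_alpha
        self.threshold_ = cvres.chosen_h
        self.sample_correlation_ = sample_correlation(X)
        self.mask_ = build_mask(self.sample_correlation_, self.threshold_)
        return self
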