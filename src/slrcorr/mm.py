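"""Low-rank correlation fitting under a binary mask via an MM algorithm.

The optimization problem is

    minimize  f(Y | R, W) = || R - W (.) Y Y^T ||_F^2
    subject to ||y_j|| = 1 for every row y_j of the p x d factor Y,

where R is a correlation matrix, W a symmetric binary mask with unit
diagonal and (.) the Hadamard product. The unit-row constraint makes
Y Y^T a correlation matrix of rank at most d.

Each row y_i enters the objective through the quadratic

    f_i(y_i) = y_i^T B_i y_i - 2 y_i^T c_i,
    B_i = sum_{j != i} w_ij y_j y_j^T,   c_i = sum_{j != i} w_ij r_ij y_j.

Because B_i - lambda_i I is negative semi-definite for lambda_i the top
eigenvalue of B_i, f_i is majorized at the current iterate y by

    g_i(y_i | y) = -y^T B_i y + 2 lambda_i - 2 y_i^T (lambda_i I - B_i) y
                   - 2 y_i^T c_i,

a linear function of y_i whose constrained minimizer has the closed form

    y_i <- (lambda_i y - B_i y + c_i) / ||lambda_i y - B_i y + c_i||.

Cycling this update over rows never increases the objective (MM descent).

The module-level functions here are the functional surface; the
scikit-learn estimator :class:`slrcorr.estimators.LowRankCorrelationMM`
wraps :func:`fit_multistart`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import masked_objective, mm_fit

__all__ = [
    "FitResult",
    "objective",
    "row_objective",
    "row_majorizer",
    "update_row",
    "random_unit_rows",
    "fit",
    "fit_multistart",
]

_ROW_NORM_TOL = 1e-8


@dataclass
class FitResult:
    """Outcome of one MM run (or the best of several restarts)."""

    Y: np.ndarray
    objective_trace: np.ndarray
    n_iter: int
    converged: bool

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])


def _check_inputs(R, W, Y=None):
    R = np.asarray(R, dtype=np.float64)
    W = np.asarray(W)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be a square matrix")
    if W.shape != R.shape:
        raise ValueError("mask shape does not match R")
    W = W.astype(bool)
    if Y is not None:
        Y = np.ascontiguousarray(Y, dtype=np.float64)
        if Y.ndim != 2 or Y.shape[0] != R.shape[0]:
            raise ValueError("Y must be p x d")
        norms = np.linalg.norm(Y, axis=1)
        if np.any(np.abs(norms - 1.0) > _ROW_NORM_TOL):
            raise ValueError("rows of Y must have unit L2 norm")
        return R, W, Y
    return R, W


def objective(Y, R, W) -> float:
    """Masked loss sum_{i != j} (r_ij - w_ij y_i^T y_j)^2.

    The diagonal is excluded: with w_ii = 1 and unit rows both sides are
    1 there and contribute nothing.
    """
    R, W, Y = _check_inputs(R, W, Y)
    return float(masked_objective(Y, R, W))


def _row_parts(i, Y, R, W):
    w = W[i].astype(np.float64).copy()
    w[i] = 0.0
    B = (Y * w[:, None]).T @ Y
    c = (w * R[i]) @ Y
    return B, c


def row_objective(i, y, Y, R, W) -> float:
    """The part of the loss that depends on row i: y^T B_i y - 2 y^T c_i."""
    B, c = _row_parts(i, np.asarray(Y, float), np.asarray(R, float), np.asarray(W, bool))
    y = np.asarray(y, float)
    return float(y @ B @ y - 2.0 * y @ c)


def row_majorizer(i, y, y_prev, Y, R, W) -> float:
    """Linear majorizer of :func:`row_objective` at ``y_prev``.

    Satisfies g(y | y_prev) >= f_i(y) for all unit y, with equality at
    y = y_prev.
    """
    B, c = _row_parts(i, np.asarray(Y, float), np.asarray(R, float), np.asarray(W, bool))
    y = np.asarray(y, float)
    y_prev = np.asarray(y_prev, float)
    lam = float(np.linalg.eigvalsh(B)[-1]) if B.size else 0.0
    return float(
        -y_prev @ B @ y_prev
        + 2.0 * lam
        - 2.0 * y @ ((lam * np.eye(len(y_prev)) - B) @ y_prev)
        - 2.0 * y @ c
    )


def update_row(i, Y, R, W) -> np.ndarray:
    """One MM update of row i; returns the new unit-norm row.

    Pure-numpy reference implementation of the kernel's inner step. If the
    update direction is degenerate (norm < 1e-12, e.g. an isolated
    variable) the previous row is returned unchanged — the objective does
    not depend on that row.
    """
    R, W, Y = _check_inputs(R, W, Y)
    B, c = _row_parts(i, Y, R, W)
    lam = float(np.linalg.eigvalsh(B)[-1])
    num = lam * Y[i] - B @ Y[i] + c
    nrm = np.linalg.norm(num)
    if nrm < 1e-12:
        return Y[i].copy()
    return num / nrm


def random_unit_rows(p, d, rng) -> np.ndarray:
    """Random p x d factor with unit-norm rows (standard-normal directions)."""
    Y = rng.standard_normal((p, d))
    Y /= np.linalg.norm(Y, axis=1, keepdims=True)
    return np.ascontiguousarray(Y)


def fit(
    R,
    W,
    d,
    init=None,
    *,
    eps: float = 1e-6,
    max_iter: int = 1000,
    relative: bool = False,
    random_state=None,
) -> FitResult:
    """Cyclic MM descent from one starting point.

    Parameters
    ----------
    R, W : p x p correlation matrix and binary mask (unit diagonals).
    d : target rank (columns of Y), d <= p.
    init : starting factor with unit rows, or None to draw one from
        ``random_state``.
    eps : stop once the objective decrease over a full sweep falls below
        this (absolute by default; relative to the current objective when
        ``relative`` is set).
    """
    R, W = _check_inputs(R, W)
    p = R.shape[0]
    if not 1 <= d <= p:
        raise ValueError(f"rank d={d} must satisfy 1 <= d <= p={p}")
    if eps <= 0:
        raise ValueError("eps must be positive")
    if init is None:
        rng = np.random.default_rng(random_state)
        Y = random_unit_rows(p, d, rng)
    else:
        _, _, Y = _check_inputs(R, W, init)
        Y = Y.copy()
        if Y.shape[1] != d:
            raise ValueError("init has wrong number of columns")
    trace, n_iter, converged = mm_fit(Y, R, W, float(eps), int(max_iter), relative)
    if not np.isfinite(trace[-1]):
        raise FloatingPointError("objective became non-finite; check inputs")
    return FitResult(Y=Y, objective_trace=np.asarray(trace), n_iter=int(n_iter), converged=bool(converged))


def fit_multistart(
    R,
    W,
    d,
    n_starts: int = 50,
    *,
    eps: float = 1e-6,
    max_iter: int = 1000,
    relative: bool = False,
    random_state=None,
) -> FitResult:
    """Best of ``n_starts`` independent random initializations.

    Starting factors are drawn sequentially from a single generator, so
    with a fixed seed the first k starts of an (k+1)-start run coincide
    with a k-start run and the best objective is non-increasing in
    ``n_starts``.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(random_state)
    best: FitResult | None = None
    R, W = _check_inputs(R, W)
    p = R.shape[0]
    for _ in range(n_starts):
        init = random_unit_rows(p, d, rng)
        res = fit(R, W, d, init=init, eps=eps, max_iter=max_iter, relative=relative)
        if best is None or res.objective < best.objective:
            best = res
    return best
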