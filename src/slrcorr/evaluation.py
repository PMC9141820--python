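"""Evaluation indices for estimated sparse correlation matrices.

Accuracy is measured by relative Frobenius- and spectral-norm errors
against the true matrix; support recovery by TPR/FPR over off-diagonal
entries; interpretability by the fraction of exactly-zero off-diagonal
entries (sparsity). For grouped-variable (gene-class) analyses where the
true structure is only known between classes, within-class sparsity and
between-class FPR are used instead.

"Zero" means exactly zero by default: the estimators in this package
produce structural zeros through the binary mask. For matrices imported
from elsewhere a small tolerance can be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EvalReport",
    "GeneClasses",
    "relative_error_fnorm",
    "relative_error_snorm",
    "tpr_fpr",
    "sparsity",
    "evaluate_estimate",
    "f_statistics",
    "within_class_sparsity",
    "between_class_fpr",
]


@dataclass
class EvalReport:
    """Bundle of the standard indices (NaN where undefined)."""

    f_norm_rel: float
    s_norm_rel: float
    tpr: float
    fpr: float
    sparsity: float


@dataclass
class GeneClasses:
    """Per-variable F statistics and the informative/non-informative split."""

    f_values: np.ndarray
    informative: np.ndarray
    noninformative: np.ndarray


def _pair(R_hat, R_true):
    A = np.asarray(R_hat, dtype=np.float64)
    B = np.asarray(R_true, dtype=np.float64)
    if A.shape != B.shape:
        raise ValueError("matrices must have the same shape")
    return A, B


def relative_error_fnorm(R_hat, R_true) -> float:
    """||R_hat - R_true||_F / ||R_true||_F."""
    A, B = _pair(R_hat, R_true)
    denom = np.linalg.norm(B, "fro")
    if denom == 0.0:
        raise ValueError("true matrix has zero Frobenius norm")
    return float(np.linalg.norm(A - B, "fro") / denom)


def relative_error_snorm(R_hat, R_true) -> float:
    """||R_hat - R_true||_2 / ||R_true||_2 (largest singular value)."""
    A, B = _pair(R_hat, R_true)
    denom = np.linalg.norm(B, 2)
    if denom == 0.0:
        raise ValueError("true matrix has zero spectral norm")
    return float(np.linalg.norm(A - B, 2) / denom)


def _offdiag_mask(p: int) -> np.ndarray:
    return ~np.eye(p, dtype=bool)


def tpr_fpr(R_hat, R_true, tol: float = 0.0, include_diagonal: bool = True) -> tuple[float, float]:
    """Support-recovery rates.

    TPR: fraction of truly nonzero entries estimated nonzero. FPR:
    fraction of truly zero entries estimated nonzero. Either is NaN when
    its denominator is empty (e.g. FPR against a dense true matrix).

    By default the counts run over all cells, the convention the printed
    reference tables follow: the unit diagonal is truly and trivially
    nonzero, so it enters the TPR numerator and denominator while leaving
    FPR untouched (diagonal entries are never truly zero). Set
    ``include_diagonal=False`` for the off-diagonal-only variant.
    """
    A, B = _pair(R_hat, R_true)
    region = np.ones(A.shape, dtype=bool) if include_diagonal else _offdiag_mask(A.shape[0])
    hat_nz = np.abs(A) > tol
    true_nz = B != 0.0
    pos = region & true_nz
    neg = region & ~true_nz
    tpr = float(np.count_nonzero(hat_nz & pos) / pos.sum()) if pos.any() else float("nan")
    fpr = float(np.count_nonzero(hat_nz & neg) / neg.sum()) if neg.any() else float("nan")
    return tpr, fpr


def sparsity(R_hat, tol: float = 0.0) -> float:
    """Fraction of exactly-zero off-diagonal entries (denominator p^2 - p)."""
    A = np.asarray(R_hat, dtype=np.float64)
    p = A.shape[0]
    if p < 2:
        raise ValueError("need p >= 2")
    off = _offdiag_mask(p)
    return float(np.count_nonzero(np.abs(A[off]) <= tol) / (p * p - p))


def evaluate_estimate(R_hat, R_true, tol: float = 0.0) -> EvalReport:
    """All standard indices for one estimate against the true matrix."""
    tpr, fpr = tpr_fpr(R_hat, R_true, tol=tol)
    return EvalReport(
        f_norm_rel=relative_error_fnorm(R_hat, R_true),
        s_norm_rel=relative_error_snorm(R_hat, R_true),
        tpr=tpr,
        fpr=fpr,
        sparsity=sparsity(R_hat, tol=tol),
    )


def f_statistics(X, class_labels, n_top: int = 40, n_bottom: int = 60) -> GeneClasses:
    """One-way ANOVA F statistic per column, with the top/bottom split.

    F_j = [ (G-1)^-1 sum_g n_g (xbar_gj - xbar_j)^2 ]
        / [ (n-G)^-1 sum_g (n_g - 1) s_gj^2 ],

    with s_gj^2 the within-class sample variance (ddof=1). Variables are
    ranked by F (infinite values — zero within-class variance but
    distinct class means — rank highest); the ``n_top`` largest form the
    informative set and the ``n_bottom`` smallest the non-informative set.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(class_labels)
    classes = np.unique(labels)
    G = classes.size
    n, p = X.shape
    if G < 2:
        raise ValueError("need at least two classes")
    if n_top + n_bottom > p:
        raise ValueError("n_top + n_bottom exceeds the number of variables")
    grand = X.mean(axis=0)
    between = np.zeros(p)
    within = np.zeros(p)
    for g in classes:
        Xg = X[labels == g]
        ng = Xg.shape[0]
        if ng < 2:
            raise ValueError(f"class {g!r} has fewer than 2 samples")
        between += ng * (Xg.mean(axis=0) - grand) ** 2
        within += (ng - 1) * Xg.var(axis=0, ddof=1)
    between /= G - 1
    within /= n - G
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(within > 0.0, between / within, np.where(between > 0.0, np.inf, np.nan))
    order = np.argsort(f, kind="stable")  # NaN (no signal, no noise) sorts last; not expected
    return GeneClasses(
        f_values=f,
        informative=np.sort(order[::-1][:n_top]),
        noninformative=np.sort(order[:n_bottom]),
    )


def _check_sets(R_hat, informative, noninformative):
    A = np.asarray(R_hat, dtype=np.float64)
    I = np.asarray(informative, dtype=int)
    N = np.asarray(noninformative, dtype=int)
    if I.size == 0 or N.size == 0:
        raise ValueError("both index sets must be nonempty")
    if np.intersect1d(I, N).size:
        raise ValueError("index sets must be disjoint")
    return A, I, N


def within_class_sparsity(R_hat, informative, noninformative, tol: float = 0.0) -> float:
    """Fraction of zero entries among within-class off-diagonal pairs.

    Ordered pairs (i, j), i != j, with both indices in the informative
    set or both in the non-informative set; the diagonal is excluded.
    """
    A, I, N = _check_sets(R_hat, informative, noninformative)
    zeros = 0
    total = 0
    for S in (I, N):
        sub = A[np.ix_(S, S)]
        off = _offdiag_mask(S.size)
        zeros += int(np.count_nonzero(np.abs(sub[off]) <= tol))
        total += S.size * (S.size - 1)
    return zeros / total


def between_class_fpr(R_hat, informative, noninformative, tol: float = 0.0) -> float:
    """Fraction of nonzero cross-class entries (denominator 2 |IS| |NS|).

    Cross-class true correlations are taken to be zero, so every nonzero
    estimated entry between the two classes is a false positive.
    """
    A, I, N = _check_sets(R_hat, informative, noninformative)
    cross = A[np.ix_(I, N)]
    return float(2 * np.count_nonzero(np.abs(cross) > tol) / (2 * I.size * N.size))
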