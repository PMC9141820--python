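"""Numba kernels for the MM inner loop.

The cyclic row-update sweep dominates the cost of everything in this
package (it runs inside every cross-validation fold), so it is compiled
with numba. All kernels operate on float64 arrays; the mask is boolean.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency in practice

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


@njit(cache=True)
def _max_eigval(B):
    """Largest eigenvalue of a small symmetric d x d matrix.

    Closed form for d <= 2 (the common case in low-rank fits); LAPACK
    otherwise.
    """
    d = B.shape[0]
    if d == 1:
        return B[0, 0]
    if d == 2:
        a = B[0, 0]
        c = B[1, 1]
        b = B[0, 1]
        m = 0.5 * (a + c)
        r = np.sqrt(0.25 * (a - c) ** 2 + b * b)
        return m + r
    return np.linalg.eigvalsh(B)[-1]


@njit(cache=True)
def masked_objective(Y, R, W):
    """sum_{i != j} (r_ij - w_ij y_i . y_j)^2 — the masked low-rank loss."""
    p, d = Y.shape
    f = 0.0
    for i in range(p):
        for j in range(p):
            if j != i:
                e = R[i, j]
                if W[i, j]:
                    s = 0.0
                    for o in range(d):
                        s += Y[i, o] * Y[j, o]
                    e -= s
                f += e * e
    return f


@njit(cache=True)
def mm_fit(Y, R, W, eps, max_iter, relative=False):
    """Run cyclic majorize-minimization row updates on Y in place.

    Each row update majorizes the row's quadratic by linearizing at the
    current iterate with the top eigenvalue of B_i = sum_{j != i, w_ij=1}
    y_j y_j^T, then renormalizes to the unit sphere. Rows are updated
    Gauss-Seidel style: B_i is rebuilt from the freshest rows.

    Returns (objective trace, iterations used, converged flag). The trace
    has one entry per completed sweep plus the initial objective and is
    non-increasing by the MM descent property.
    """
    p, d = Y.shape
    Bi = np.empty((d, d))
    v = np.empty(d)
    num = np.empty(d)
    trace = np.empty(max_iter + 1)
    f_prev = masked_objective(Y, R, W)
    trace[0] = f_prev
    n_iter = 0
    converged = False
    for t in range(max_iter):
        for i in range(p):
            for a in range(d):
                v[a] = 0.0
                for b in range(d):
                    Bi[a, b] = 0.0
            for j in range(p):
                if j != i and W[i, j]:
                    r = R[i, j]
                    for a in range(d):
                        ya = Y[j, a]
                        v[a] += r * ya
                        for b in range(d):
                            Bi[a, b] += ya * Y[j, b]
            lam = _max_eigval(Bi)
            nrm = 0.0
            for a in range(d):
                s = lam * Y[i, a] + v[a]
                for b in range(d):
                    s -= Bi[a, b] * Y[i, b]
                num[a] = s
                nrm += s * s
            nrm = np.sqrt(nrm)
            # Degenerate numerator: the objective is flat in this row
            # (e.g. an isolated variable); keep the previous iterate.
            if nrm > 1e-12:
                for a in range(d):
                    Y[i, a] = num[a] / nrm
        f = masked_objective(Y, R, W)
        n_iter = t + 1
        trace[n_iter] = f
        tol = eps * max(1.0, f_prev) if relative else eps
        if f_prev - f < tol:
            converged = True
            break
        f_prev = f
    return trace[: n_iter + 1], n_iter, converged
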