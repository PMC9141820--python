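import numpy as np
import pytest

from slrcorr import fit, fit_multistart, objective, update_row
from slrcorr.mm import random_unit_rows, row_majorizer, row_objective

from conftest import random_correlation, random_mask


def test_objective_masked_out_entries_are_constant(rng):
    R = random_correlation(rng, 4)
    W = np.eye(4, dtype=bool)  # off-diagonal all masked out
    Y1 = random_unit_rows(4, 2, rng)
    Y2 = random_unit_rows(4, 2, rng)
    expected = np.sum(R**2) - 4.0  # sum of squared off-diagonals
    assert objective(Y1, R, W) == pytest.approx(expected)
    assert objective(Y2, R, W) == pytest.approx(expected)


def test_objective_hand_example():
    R = np.array([[1.0, 0.9], [0.9, 1.0]])
    W = np.ones((2, 2), dtype=bool)
    Y = np.array([[1.0], [1.0]])
    assert objective(Y, R, W) == pytest.approx(2 * (0.9 - 1.0) ** 2)


def test_objective_exact_fit_is_zero():
    Y = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
    R = Y @ Y.T
    np.fill_diagonal(R, 1.0)
    W = np.ones((3, 3), dtype=bool)
    assert objective(Y, R, W) == pytest.approx(0.0, abs=1e-15)


def test_objective_rejects_non_unit_rows():
    R = np.eye(2)
    with pytest.raises(ValueError, match="unit"):
        objective(np.array([[2.0], [1.0]]), R, np.ones((2, 2), bool))


def test_update_row_isolated_variable_keeps_previous(rng):
    R = random_correlation(rng, 3)
    W = np.eye(3, dtype=bool)
    Y = random_unit_rows(3, 2, rng)
    assert np.array_equal(update_row(0, Y, R, W), Y[0])


def test_update_row_hand_example():
    # p=2, d=1, r12=0.9, y2=1, y1=-1: numerator = 1*(-1) - 1*(-1) + 0.9 = 0.9
    R = np.array([[1.0, 0.9], [0.9, 1.0]])
    W = np.ones((2, 2), dtype=bool)
    Y = np.array([[-1.0], [1.0]])
    assert update_row(0, Y, R, W) == pytest.approx([1.0])


def test_update_row_returns_unit_norm(rng):
    for _ in range(20):
        p, d = rng.integers(2, 8), rng.integers(1, 4)
        R = random_correlation(rng, p)
        W = random_mask(rng, p)
        Y = random_unit_rows(p, d, rng)
        new = update_row(int(rng.integers(p)), Y, R, W)
        assert np.linalg.norm(new) == pytest.approx(1.0, abs=1e-12)


def test_update_row_never_increases_objective(rng):
    for _ in range(20):
        p, d = int(rng.integers(2, 8)), int(rng.integers(1, 4))
        R = random_correlation(rng, p)
        W = random_mask(rng, p)
        Y = random_unit_rows(p, d, rng)
        i = int(rng.integers(p))
        before = objective(Y, R, W)
        Y2 = Y.copy()
        Y2[i] = update_row(i, Y, R, W)
        assert objective(Y2, R, W) <= before + 1e-10


def test_majorizer_bounds_row_objective(rng):
    for _ in range(10):
        p, d = int(rng.integers(2, 7)), int(rng.integers(1, 4))
        R = random_correlation(rng, p)
        W = random_mask(rng, p)
        Y = random_unit_rows(p, d, rng)
        i = int(rng.integers(p))
        y_prev = Y[i]
        assert row_majorizer(i, y_prev, y_prev, Y, R, W) == pytest.approx(
            row_objective(i, y_prev, Y, R, W), abs=1e-10
        )
        for _ in range(20):
            y = rng.standard_normal(d)
            y /= np.linalg.norm(y)
            assert row_majorizer(i, y, y_prev, Y, R, W) >= row_objective(i, y, Y, R, W) - 1e-10


def test_fit_two_variable_closed_form():
    R = np.array([[1.0, 0.9], [0.9, 1.0]])
    W = np.ones((2, 2), dtype=bool)
    res = fit_multistart(R, W, 1, n_starts=5, random_state=0)
    assert res.objective == pytest.approx(2 * (0.9 - 1.0) ** 2, abs=1e-10)
    assert abs(res.Y[0, 0] * res.Y[1, 0]) == pytest.approx(1.0, abs=1e-8)


def test_fit_identity_mask_converges_immediately(rng):
    R = random_correlation(rng, 5)
    res = fit(R, np.eye(5, dtype=bool), 2, random_state=0)
    assert res.converged
    assert np.ptp(res.objective_trace) == pytest.approx(0.0, abs=1e-12)


def test_fit_trace_monotone_and_rows_unit(rng):
    for _ in range(10):
        p, d = int(rng.integers(3, 10)), int(rng.integers(1, 4))
        R = random_correlation(rng, p)
        W = random_mask(rng, p)
        res = fit(R, W, d, random_state=int(rng.integers(2**31)))
        assert np.all(np.diff(res.objective_trace) <= 1e-10)
        assert np.linalg.norm(res.Y, axis=1) == pytest.approx(np.ones(p), abs=1e-10)


def test_multistart_single_start_equals_fit(rng):
    R = random_correlation(rng, 6)
    W = random_mask(rng, 6)
    a = fit_multistart(R, W, 2, n_starts=1, random_state=3)
    b = fit(R, W, 2, random_state=3)
    assert np.array_equal(a.Y, b.Y)


def test_multistart_nested_starts_never_worse(rng):
    R = random_correlation(rng, 8)
    W = random_mask(rng, 8)
    objs = [fit_multistart(R, W, 2, n_starts=k, random_state=11).objective for k in (1, 3, 6)]
    assert objs[0] >= objs[1] >= objs[2]


def test_multistart_beats_spectral_oracle():
    # Truncated-eigendecomposition rank-2 factor (rows renormalized) is a
    # feasible point, so the multistart optimum can only be better.
    from slrcorr import build_true_model

    R = build_true_model(1, 6).matrix
    W = np.ones((6, 6), dtype=bool)
    w, V = np.linalg.eigh(R)
    Y0 = V[:, -2:] * np.sqrt(w[-2:])
    Y0 /= np.linalg.norm(Y0, axis=1, keepdims=True)
    res = fit_multistart(R, W, 2, n_starts=20, random_state=0)
    assert res.objective <= objective(Y0, R, W) + 1e-10


def test_fit_validates_arguments(rng):
    R = random_correlation(rng, 4)
    W = np.ones((4, 4), dtype=bool)
    with pytest.raises(ValueError):
        fit(R, W, 5)  # d > p
    with pytest.raises(ValueError):
        fit(R, W, 2, eps=0.0)
    with pytest.raises(ValueError):
        fit(R, np.ones((3, 3), bool), 2)
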