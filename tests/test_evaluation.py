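import numpy as np
import pytest
from scipy import stats

from slrcorr import (
    between_class_fpr,
    f_statistics,
    relative_error_fnorm,
    relative_error_snorm,
    sparsity,
    tpr_fpr,
    within_class_sparsity,
)

from conftest import random_correlation


def test_relative_errors_identities(rng):
    R = random_correlation(rng, 5)
    assert relative_error_fnorm(R, R) == 0.0
    assert relative_error_snorm(R, R) == 0.0
    assert relative_error_fnorm(2 * R, R) == pytest.approx(1.0)
    assert relative_error_snorm(2 * R, R) == pytest.approx(1.0)


def test_relative_error_fnorm_hand_2x2():
    A = np.array([[1.0, 0.5], [0.5, 1.0]])
    B = np.array([[1.0, 0.1], [0.1, 1.0]])
    expected = np.sqrt(2 * 0.4**2) / np.sqrt(2 + 2 * 0.01)
    assert relative_error_fnorm(A, B) == pytest.approx(expected)


def test_snorm_diagonal_closed_form():
    A = np.diag([3.0, 1.0])
    B = np.diag([1.0, 2.0])
    assert relative_error_snorm(A, B) == pytest.approx(2.0 / 2.0)


def test_snorm_of_difference_below_fnorm(rng):
    A, B = random_correlation(rng, 6), random_correlation(rng, 6)
    assert np.linalg.norm(A - B, 2) <= np.linalg.norm(A - B, "fro") + 1e-12


def test_tpr_fpr_trivial_cases():
    truth = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.0], [0.0, 0.0, 1.0]])
    assert tpr_fpr(truth, truth) == (1.0, 0.0)
    # identity estimate: only the (trivially nonzero) diagonal is recovered
    assert tpr_fpr(np.eye(3), truth) == (pytest.approx(3 / 5), 0.0)
    assert tpr_fpr(np.eye(3), truth, include_diagonal=False) == (0.0, 0.0)


def test_tpr_fpr_one_fp_one_fn():
    truth = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.2], [0.0, 0.2, 1.0]])
    est = np.array([[1.0, 0.4, 0.1], [0.4, 1.0, 0.0], [0.1, 0.0, 1.0]])
    tpr, fpr = tpr_fpr(est, truth)
    assert tpr == pytest.approx(5 / 7)  # (1,2) pair missed; diagonal counted
    assert fpr == pytest.approx(2 / 2)  # (1,3) pair falsely detected
    tpr_off, fpr_off = tpr_fpr(est, truth, include_diagonal=False)
    assert tpr_off == pytest.approx(2 / 4)
    assert fpr_off == fpr  # diagonal never contributes to FPR


def test_fpr_undefined_for_dense_truth(rng):
    dense = random_correlation(rng, 4)
    tpr, fpr = tpr_fpr(dense, dense)
    assert tpr == 1.0 and np.isnan(fpr)


def test_rates_match_exhaustive_counts(rng):
    for _ in range(100):
        p = 6
        est = np.where(rng.random((p, p)) < 0.5, rng.uniform(-1, 1, (p, p)), 0.0)
        truth = np.where(rng.random((p, p)) < 0.5, rng.uniform(-1, 1, (p, p)), 0.0)
        est, truth = (M + M.T for M in (est, truth))
        np.fill_diagonal(est, 1.0)
        np.fill_diagonal(truth, 1.0)
        tp = fp = pos = neg = zeros = 0
        for i in range(p):
            for j in range(p):
                if truth[i, j] != 0:
                    pos += 1
                    tp += est[i, j] != 0
                else:
                    neg += 1
                    fp += est[i, j] != 0
                if i != j:
                    zeros += est[i, j] == 0
        tpr, fpr = tpr_fpr(est, truth)
        if pos:
            assert tpr == tp / pos
        if neg:
            assert fpr == fp / neg
        assert sparsity(est) == zeros / (p * p - p)
        assert sparsity(est) + np.count_nonzero(est[~np.eye(p, dtype=bool)]) / (p * p - p) == 1.0


def test_sparsity_extremes(rng):
    dense = random_correlation(rng, 4)
    assert sparsity(dense) == 0.0
    assert sparsity(np.eye(4)) == 1.0


def test_sparsity_single_zero_pair():
    R = np.ones((3, 3))
    R[0, 1] = R[1, 0] = 0.0
    assert sparsity(R) == pytest.approx(2 / 6)


def test_f_statistics_matches_scipy(rng):
    X = rng.standard_normal((30, 8))
    labels = np.repeat([0, 1, 2], 10)
    X[labels == 1] += rng.normal(0, 1, 8)
    gc = f_statistics(X, labels, n_top=3, n_bottom=3)
    for j in range(8):
        f_ref = stats.f_oneway(*(X[labels == g, j] for g in range(3))).statistic
        assert gc.f_values[j] == pytest.approx(f_ref)
    assert np.intersect1d(gc.informative, gc.noninformative).size == 0


def test_f_statistic_two_classes_equals_squared_t(rng):
    X = rng.standard_normal((20, 5))
    labels = np.repeat([0, 1], 10)
    gc = f_statistics(X, labels, n_top=2, n_bottom=2)
    for j in range(5):
        t = stats.ttest_ind(X[labels == 0, j], X[labels == 1, j], equal_var=True).statistic
        assert gc.f_values[j] == pytest.approx(t**2)


def test_f_statistic_degenerate_variable_ranks_top(rng):
    X = rng.standard_normal((20, 4))
    labels = np.repeat([0, 1], 10)
    X[:, 2] = labels  # zero within-class variance, distinct means
    gc = f_statistics(X, labels, n_top=1, n_bottom=1)
    assert np.isinf(gc.f_values[2])
    assert gc.informative.tolist() == [2]


def test_noise_variable_f_mean_matches_f_distribution():
    rng = np.random.default_rng(0)
    n, G = 40, 4
    labels = np.repeat(np.arange(G), n // G)
    means = []
    for _ in range(200):
        X = rng.standard_normal((n, 2))
        means.append(f_statistics(X, labels, n_top=1, n_bottom=1).f_values)
    means = np.concatenate(means)
    dfd = n - G
    expected = dfd / (dfd - 2)
    se = np.std(means, ddof=1) / np.sqrt(means.size)
    assert abs(means.mean() - expected) < 3 * se


def test_within_class_sparsity_extremes_and_counts():
    p = 100
    info = np.arange(40)
    noninfo = np.arange(40, 100)
    dense = np.ones((p, p))
    assert within_class_sparsity(dense, info, noninfo) == 0.0
    assert within_class_sparsity(np.zeros((p, p)), info, noninfo) == 1.0
    # dense within informative, zero within non-informative
    M = np.zeros((p, p))
    M[np.ix_(info, info)] = 1.0
    assert within_class_sparsity(M, info, noninfo) == pytest.approx(
        (60 * 59) / (40 * 39 + 60 * 59)
    )


def test_between_class_fpr_counts():
    info = np.arange(40)
    noninfo = np.arange(40, 100)
    assert between_class_fpr(np.zeros((100, 100)), info, noninfo) == 0.0
    assert between_class_fpr(np.ones((100, 100)), info, noninfo) == 1.0
    M = np.zeros((100, 100))
    flat = np.zeros(40 * 60, dtype=bool)
    flat[:240] = True  # 240 ordered-pair halves -> 480 symmetric entries
    M[np.ix_(info, noninfo)] = flat.reshape(40, 60)
    M += M.T
    assert between_class_fpr(M, info, noninfo) == pytest.approx(480 / 4800)


def test_disjointness_enforced():
    with pytest.raises(ValueError):
        within_class_sparsity(np.eye(5), [0, 1], [1, 2])
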