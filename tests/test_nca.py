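"""NCA weighting: brute-force oracles, gradient checks, optimisation behaviour."""

import numpy as np
import pytest

from conftest import random_small_instance
from fundusnet.nca import (
    NCAConfig,
    fit_nca,
    nca_gradient,
    nca_objective,
    nca_probabilities,
    select_by_weight,
)


def oracle_probabilities(X, y, w, sigma=1.0):
    """Direct enumeration of the soft-neighbour kernel over all pairs."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    n = X.shape[0]
    P = np.zeros(n)
    for i in range(n):
        kernel = np.zeros(n)
        for j in range(n):
            if j == i:
                continue
            d = sum(w[r] ** 2 * abs(X[i, r] - X[j, r]) for r in range(X.shape[1]))
            kernel[j] = np.exp(-d / sigma)
        total = kernel.sum()
        for j in range(n):
            if j != i and y[j] == y[i]:
                P[i] += kernel[j] / total
    return P


class TestProbabilities:
    def test_one_sample_per_class_has_no_hits(self):
        P = nca_probabilities(np.array([[0.0], [1.0]]), np.array([0, 1]), np.ones(1))
        np.testing.assert_allclose(P, [0.0, 0.0])

    def test_two_samples_same_class_take_all_mass(self):
        P = nca_probabilities(np.array([[0.0], [1.0]]), np.array([0, 0]), np.ones(1))
        np.testing.assert_allclose(P, [1.0, 1.0])

    def test_three_point_example_matches_enumeration(self):
        X = np.array([[0.0], [0.1], [1.0]])
        y = np.array(["A", "A", "B"])
        w = np.ones(1)
        np.testing.assert_allclose(
            nca_probabilities(X, y, w, sigma=1.0), oracle_probabilities(X, y, w), atol=1e-12
        )

    def test_rows_of_neighbour_matrix_sum_to_one(self):
        for seed in range(5):
            X, y = random_small_instance(seed)
            P = nca_probabilities(X, y, np.ones(X.shape[1]))
            assert np.all(P >= -1e-10) and np.all(P <= 1 + 1e-10)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            nca_probabilities(np.array([[1.0]]), np.array([0]), np.ones(1))


class TestObjective:
    def test_one_per_class_reduces_to_penalty(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([0, 1, 2])
        cfg = NCAConfig(lambda_reg=0.3)
        w = np.array([1.7])
        assert nca_objective(X, y, w, cfg) == pytest.approx(-0.3 * 1.7**2)

    def test_zero_weights_give_uniform_neighbour_mass(self):
        # all distances zero -> p_ij = 1/(n-1); P_i = (same-class count - 1)/(n-1)
        X = np.random.default_rng(0).normal(size=(6, 3))
        y = np.array([0, 0, 0, 1, 1, 1])
        cfg = NCAConfig(lambda_reg=0.0)
        assert nca_objective(X, y, np.zeros(3), cfg) == pytest.approx(2 / 5)

    def test_toy_value_matches_enumeration(self):
        X = np.array([[0.0], [0.1], [1.0]])
        y = np.array(["A", "A", "B"])
        cfg = NCAConfig(lambda_reg=0.25)
        expected = oracle_probabilities(X, y, np.ones(1)).mean() / 1.0 - 0.25
        assert nca_objective(X, y, np.ones(1), cfg) == pytest.approx(expected, abs=1e-12)


class TestGradient:
    def test_penalty_gradient_vanishes_at_zero_weights(self):
        X = np.array([[0.0, 1.0], [1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([0, 0, 1, 1])
        g = nca_gradient(X, y, np.zeros(2), NCAConfig(lambda_reg=0.5))
        np.testing.assert_allclose(g, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_central_finite_differences(self, seed):
        X, y = random_small_instance(seed)
        rng = np.random.default_rng(seed + 1000)
        w = rng.normal(size=X.shape[1])
        cfg = NCAConfig(lambda_reg=0.1)
        g = nca_gradient(X, y, w, cfg)
        eps = 1e-5
        fd = np.zeros_like(w)
        for r in range(len(w)):
            wp, wm = w.copy(), w.copy()
            wp[r] += eps
            wm[r] -= eps
            fd[r] = (nca_objective(X, y, wp, cfg) - nca_objective(X, y, wm, cfg)) / (2 * eps)
        scale = max(1e-8, np.abs(fd).max())
        assert np.abs(g - fd).max() / scale < 1e-6

    def test_duplicate_columns_get_identical_components(self):
        rng = np.random.default_rng(3)
        col = rng.normal(size=(8, 1))
        X = np.hstack([col, col, rng.normal(size=(8, 1))])
        y = np.array([0, 0, 1, 1, 0, 1, 0, 1])
        g = nca_gradient(X, y, np.ones(3), NCAConfig(lambda_reg=0.1))
        assert g[0] == pytest.approx(g[1], rel=1e-12)


class TestFit:
    def test_large_regularization_collapses_weights(self):
        X, y = random_small_instance(1, n_max=10)
        res = fit_nca(X, y, NCAConfig(lambda_reg=10.0, max_iters=200))
        assert np.abs(res.w).max() < 0.05

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 2))
        with pytest.raises(ValueError, match="unidentified"):
            fit_nca(X, np.zeros(5))

    def test_objective_trace_is_monotone(self):
        X, y = random_small_instance(2)
        res = fit_nca(X, y, NCAConfig())
        diffs = np.diff(res.objective_trace)
        assert np.all(diffs >= -1e-12)

    def test_lbfgs_trace_is_monotone_and_reaches_higher_objective(self):
        X, y = random_small_instance(4, n_max=10, p_max=4)
        ga = fit_nca(X, y, NCAConfig(max_iters=50))
        lb = fit_nca(X, y, NCAConfig(solver="lbfgs", max_iters=200))
        assert np.all(np.diff(lb.objective_trace) >= -1e-9)
        assert lb.objective_trace[-1] >= ga.objective_trace[-1] - 1e-6

    def test_informative_feature_outweighs_noise(self):
        # feature 1 separates tight clusters, feature 2 is pure noise
        rng = np.random.default_rng(7)
        n = 60
        y = np.repeat([0, 1], n // 2)
        X = np.column_stack([y * 4.0 + rng.normal(0, 0.3, n), rng.normal(0, 1.0, n)])
        res = fit_nca(X, y, NCAConfig(seed=7))
        assert res.w[0] > res.w[1]
        # grid oracle: F over (w1, w2) is maximised with w1 > w2
        Xs = (X - X.mean(0)) / X.std(0)
        cfg = NCAConfig(lambda_reg=1.0 / n, standardize=False)
        grid = np.linspace(0, 3, 13)
        vals = {(a, b): nca_objective(Xs, y, np.array([a, b]), cfg) for a in grid for b in grid}
        (w1_best, w2_best) = max(vals, key=vals.get)
        assert w1_best > w2_best

    def test_one_feature_fit_matches_grid_search(self):
        rng = np.random.default_rng(9)
        n = 30
        y = np.repeat([0, 1], n // 2)
        X = (y * 2.0 + rng.normal(0, 0.5, n)).reshape(-1, 1)
        cfg = NCAConfig(lambda_reg=0.25, max_iters=300)
        res = fit_nca(X, y, cfg)
        Xs = (X - X.mean()) / X.std()
        grid = np.linspace(0, 2, 2001)
        obj = [nca_objective(Xs, y, np.array([g]), NCAConfig(lambda_reg=0.25, standardize=False)) for g in grid]
        w_grid = grid[int(np.argmax(obj))]
        assert res.w[0] == pytest.approx(w_grid, abs=1e-2)

    def test_column_permutation_equivariance(self):
        X, y = random_small_instance(5, n_max=10, p_max=4)
        if X.shape[1] < 2:
            X = np.hstack([X, X + 1.0])
        perm = np.random.default_rng(0).permutation(X.shape[1])
        res = fit_nca(X, y, NCAConfig(seed=1))
        res_p = fit_nca(X[:, perm], y, NCAConfig(seed=1))
        np.testing.assert_allclose(res_p.w, res.w[perm], atol=1e-10)


class TestSelectByWeight:
    def test_boundary_is_inclusive(self):
        mask = select_by_weight(np.array([0.0004, 0.0005, 0.1]), 0.0005)
        np.testing.assert_array_equal(mask, [False, True, True])

    def test_minus_infinity_keeps_everything(self):
        assert select_by_weight(np.array([-5.0, 0.0, 3.0]), -np.inf).all()

    def test_empty_selection_warns(self):
        with pytest.warns(UserWarning, match="removes every feature"):
            mask = select_by_weight(np.array([0.1, 0.2]), 0.5)
        assert not mask.any()
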