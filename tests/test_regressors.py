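"""The three model families against independent oracles and their contracts."""

import numpy as np
import pytest

from scfsol.regressors import (
    PiecewisePolynomialRegressor,
    RBFKernelRidgeRegressor,
    TweedieGLMRegressor,
    polynomial_basis,
    solve_kernel_ridge_dual,
    tweedie_unit_deviance,
)


def piecewise_step_data():
    """12 points from two linear regimes split at T_s = 0."""
    T = np.array([-1.5, -1.2, -0.9, -0.6, -0.4, -0.1, 0.1, 0.4, 0.6, 0.9, 1.2, 1.5])
    P = np.array([-1.0, 0.5, -0.2, 1.0, -0.8, 0.3, -0.5, 0.8, -1.0, 0.2, 0.7, -0.3])
    y = np.where(T < 0, 1.0 + 0.5 * T, 5.0 + 2.0 * T)
    return np.column_stack([T, P]), y


class TestPiecewisePolynomial:
    def test_exact_linear_data_single_segment(self, rng):
        X = rng.normal(size=(30, 2))
        y = 2.0 + 3.0 * X[:, 0]
        m = PiecewisePolynomialRegressor(degree=1, max_segments=4, penalty_weight=0.0).fit(X, y)
        assert m.n_leaves_ == 1
        assert m.train_rss_ == pytest.approx(0.0, abs=1e-20)
        assert m._leaf_coefs_[0][:2] == pytest.approx([2.0, 3.0], abs=1e-8)

    def test_two_regime_split_matches_exhaustive_search(self):
        """The greedy first split must coincide with brute force over every
        candidate single split, and the two-leaf fit must be exact."""
        X, y = piecewise_step_data()
        m = PiecewisePolynomialRegressor(degree=1, max_segments=2, penalty_weight=1e-12).fit(X, y)
        assert m.n_leaves_ == 2
        node = m.tree_
        # brute-force oracle over all axis/threshold candidates
        best = (np.inf, None, None)
        for axis in (0, 1):
            uniq = np.unique(X[:, axis])
            for thr in (uniq[:-1] + uniq[1:]) / 2:
                left, right = X[:, axis] < thr, X[:, axis] >= thr
                if left.sum() < 3 or right.sum() < 3:
                    continue
                rss = 0.0
                for sel in (left, right):
                    B = polynomial_basis(X[sel], 1)
                    coef, *_ = np.linalg.lstsq(B, y[sel], rcond=None)
                    rss += float(np.sum((y[sel] - B @ coef) ** 2))
                if rss < best[0]:
                    best = (rss, axis, thr)
        assert node["axis"] == best[1]
        assert node["threshold"] == pytest.approx(best[2])
        assert -0.1 < node["threshold"] < 0.1  # between the two regimes
        assert m.train_rss_ < 1e-10

    def test_huge_penalty_forces_global_polynomial(self):
        X, y = piecewise_step_data()
        m = PiecewisePolynomialRegressor(degree=1, max_segments=6, penalty_weight=1e6).fit(X, y)
        assert m.n_leaves_ == 1

    def test_rss_non_increasing_in_max_segments(self):
        X, y = piecewise_step_data()
        y = y + np.sin(3 * X[:, 0])  # structure beyond two segments
        rss = [
            PiecewisePolynomialRegressor(degree=1, max_segments=k).fit(X, y).train_rss_
            for k in (1, 2, 3, 4)
        ]
        assert all(a >= b - 1e-15 for a, b in zip(rss, rss[1:]))

    def test_boundary_point_routed_to_upper_child(self):
        X, y = piecewise_step_data()
        m = PiecewisePolynomialRegressor(degree=1, max_segments=2).fit(X, y)
        thr = m.tree_["threshold"]
        right_leaf = m.tree_["right"]["leaf"]
        assert m._route(np.array([thr, 0.0])) == right_leaf

    def test_prediction_at_training_points_is_leaf_fit(self):
        X, y = piecewise_step_data()
        m = PiecewisePolynomialRegressor(degree=1, max_segments=2).fit(X, y)
        assert m.predict(X) == pytest.approx(y, abs=1e-8)

    def test_insufficient_rows_named_error(self):
        X = np.ones((4, 2)) * np.arange(4)[:, None]
        with pytest.raises(ValueError, match="degree-2"):
            PiecewisePolynomialRegressor(degree=2).fit(X, np.arange(4.0))

    def test_row_order_invariance(self, rng):
        X, y = piecewise_step_data()
        perm = rng.permutation(len(y))
        a = PiecewisePolynomialRegressor(degree=1, max_segments=3).fit(X, y)
        b = PiecewisePolynomialRegressor(degree=1, max_segments=3).fit(X[perm], y[perm])
        q = rng.normal(size=(20, 2))
        assert a.predict(q) == pytest.approx(b.predict(q), rel=1e-9, abs=1e-12)


class TestKernelRidge:
    def test_tiny_ridge_interpolates(self, rng):
        X = rng.normal(size=(12, 2))
        y = np.sin(X[:, 0]) + X[:, 1] ** 2
        m = RBFKernelRidgeRegressor(ridge_weight=1e-12, gamma=0.5).fit(X, y)
        assert np.max(np.abs(m.predict(X) - y)) < 1e-6

    def test_huge_ridge_shrinks_to_zero(self, rng):
        X = rng.normal(size=(15, 2))
        y = rng.normal(size=15)
        m = RBFKernelRidgeRegressor(ridge_weight=1e8, gamma=1.0).fit(X, y)
        assert np.max(np.abs(m.predict(X))) < 1e-6

    def test_two_point_system_matches_hand_solve(self):
        """2x2 dual system inverted by hand: K = [[1, e^-g], [e^-g, 1]]."""
        X = np.array([[0.0, 0.0], [1.0, 0.0]])
        y = np.array([1.0, 2.0])
        lam, gamma = 0.1, 1.0
        m = RBFKernelRidgeRegressor(ridge_weight=lam, gamma=gamma).fit(X, y)
        k = np.exp(-gamma)
        a = 1.0 + lam * 2  # diagonal of K + lam*N*I
        det = a * a - k * k
        alpha_hand = np.array([(a * 1.0 - k * 2.0) / det, (a * 2.0 - k * 1.0) / det])
        assert m.dual_coef_ == pytest.approx(alpha_hand, abs=1e-12)

    def test_dual_equals_explicit_linear_ridge(self, rng):
        """On a 5-point instance the dual solve with a linear Gram matrix
        reproduces primal ridge regression in feature space."""
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        lam, n = 0.3, 5
        alpha = solve_kernel_ridge_dual(X @ X.T, y, lam)
        beta = np.linalg.solve(X.T @ X + lam * n * np.eye(2), X.T @ y)
        assert X @ X.T @ alpha == pytest.approx(X @ beta, abs=1e-10)

    def test_matches_sklearn_kernel_ridge(self, rng):
        """Independent library cross-check of the RBF dual solution."""
        from sklearn.kernel_ridge import KernelRidge

        X = rng.normal(size=(20, 2))
        y = rng.normal(size=20)
        lam, gamma = 1e-3, 0.7
        ours = RBFKernelRidgeRegressor(ridge_weight=lam, gamma=gamma).fit(X, y)
        ref = KernelRidge(alpha=lam * 20, kernel="rbf", gamma=gamma).fit(X, y)
        q = rng.normal(size=(10, 2))
        assert ours.predict(q) == pytest.approx(ref.predict(q), abs=1e-10)

    def test_training_mse_non_decreasing_in_ridge(self, rng):
        X = rng.normal(size=(25, 2))
        y = np.sin(X[:, 0])
        mses = []
        for lam in np.logspace(-10, 2, 9):
            m = RBFKernelRidgeRegressor(ridge_weight=lam, gamma=1.0).fit(X, y)
            mses.append(np.mean((m.predict(X) - y) ** 2))
        assert all(a <= b + 1e-15 for a, b in zip(mses, mses[1:]))

    def test_symmetric_problem_symmetric_predictions(self):
        X = np.array([[-2.0, 0.0], [-1.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        y = np.array([4.0, 1.0, 1.0, 4.0])
        m = RBFKernelRidgeRegressor(ridge_weight=1e-3, gamma=0.5).fit(X, y)
        q = np.array([[0.7, 0.0], [-0.7, 0.0]])
        pred = m.predict(q)
        assert pred[0] == pytest.approx(pred[1], rel=1e-12)

    def test_far_query_decays_to_zero(self, rng):
        X = rng.normal(size=(10, 2))
        y = rng.normal(size=10)
        m = RBFKernelRidgeRegressor(ridge_weight=1e-3, gamma=1.0).fit(X, y)
        assert m.predict(np.array([[100.0, 100.0]]))[0] == pytest.approx(0.0, abs=1e-12)

    def test_row_order_invariance(self, rng):
        X = rng.normal(size=(15, 2))
        y = rng.normal(size=15)
        perm = rng.permutation(15)
        a = RBFKernelRidgeRegressor(1e-3, 1.0).fit(X, y)
        b = RBFKernelRidgeRegressor(1e-3, 1.0).fit(X[perm], y[perm])
        q = rng.normal(size=(8, 2))
        assert a.predict(q) == pytest.approx(b.predict(q), rel=1e-9, abs=1e-12)


class TestTweedieDeviance:
    @pytest.mark.parametrize("p", [1.2, 1.5, 1.9, 2.0])
    def test_zero_at_the_mean(self, p):
        assert tweedie_unit_deviance(1.0, 1.0, p) == pytest.approx(0.0, abs=1e-14)

    def test_gamma_limit_closed_form(self):
        # p = 2: d(2, 1) = 2 (1 - ln 2)
        assert tweedie_unit_deviance(2.0, 1.0, 2.0) == pytest.approx(2 * (1 - np.log(2)), rel=1e-14)

    def test_positive_off_the_mean(self, rng):
        y = rng.uniform(0.1, 5.0, 50)
        u = rng.uniform(0.1, 5.0, 50)
        for p in (1.3, 1.7, 2.0):
            d = tweedie_unit_deviance(y, u, p)
            assert np.all(d[np.abs(y - u) > 1e-12] > 0)

    def test_unsupported_power_rejected(self):
        for p in (0.5, 1.0, 2.5):
            with pytest.raises(ValueError):
                tweedie_unit_deviance(1.0, 1.0, p)

    def test_zero_target_allowed_between_one_and_two(self):
        assert np.isfinite(tweedie_unit_deviance(0.0, 1.0, 1.5))
        with pytest.raises(ValueError):
            tweedie_unit_deviance(0.0, 1.0, 2.0)


class TestTweedieGLM:
    def test_gamma_case_matches_statsmodels(self, rng):
        """IRLS quasi-likelihood at p=2 equals an independent gamma GLM."""
        import statsmodels.api as sm

        X = rng.normal(size=(60, 2))
        mu = np.exp(0.3 + 0.8 * X[:, 0] - 0.5 * X[:, 1])
        y = rng.gamma(shape=5.0, scale=mu / 5.0)
        ours = TweedieGLMRegressor(power=2.0).fit(X, y)
        ref = sm.GLM(
            y, sm.add_constant(X), family=sm.families.Gamma(sm.families.links.Log())
        ).fit()
        assert ours.intercept_ == pytest.approx(ref.params[0], abs=1e-6)
        assert ours.coef_ == pytest.approx(ref.params[1:], abs=1e-6)

    def test_tweedie_power_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        X = rng.normal(size=(60, 2))
        mu = np.exp(0.2 + 0.5 * X[:, 0])
        y = rng.gamma(shape=3.0, scale=mu / 3.0)
        ours = TweedieGLMRegressor(power=1.6).fit(X, y)
        ref = sm.GLM(
            y, sm.add_constant(X),
            family=sm.families.Tweedie(sm.families.links.Log(), var_power=1.6),
        ).fit()
        assert ours.intercept_ == pytest.approx(ref.params[0], abs=1e-6)
        assert ours.coef_ == pytest.approx(ref.params[1:], abs=1e-6)

    def test_noiseless_exponential_recovered_exactly(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.exp(0.7 + 0.4 * X[:, 0])
        m = TweedieGLMRegressor(power=1.5).fit(X, y)
        assert m.intercept_ == pytest.approx(0.7, abs=1e-8)
        assert m.coef_ == pytest.approx([0.4, 0.0], abs=1e-8)

    def test_constant_targets_intercept_only(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.full(10, 3.0)
        m = TweedieGLMRegressor(power=1.5).fit(X, y)
        assert np.exp(m.intercept_) == pytest.approx(3.0, rel=1e-8)
        assert m.coef_ == pytest.approx([0.0, 0.0], abs=1e-7)

    def test_pearson_residuals_centered(self, rng):
        X = rng.normal(size=(80, 2))
        mu = np.exp(0.1 + 0.6 * X[:, 0])
        y = rng.gamma(shape=4.0, scale=mu / 4.0)
        m = TweedieGLMRegressor(power=1.8).fit(X, y)
        u = m.predict(X)
        pearson = (y - u) / np.sqrt(u**m.power_)
        assert abs(pearson.mean()) < 0.05

    def test_predictions_strictly_positive(self, rng):
        X = rng.normal(size=(30, 2))
        y = rng.gamma(2.0, 1.0, size=30)
        m = TweedieGLMRegressor(power=1.5).fit(X, y)
        assert np.all(m.predict(rng.normal(size=(100, 2)) * 3) > 0)

    def test_monotone_when_coefficient_positive(self, rng):
        X = rng.normal(size=(30, 2))
        y = np.exp(0.2 + 0.9 * X[:, 0])
        m = TweedieGLMRegressor(power=1.5).fit(X, y)
        t = np.linspace(-2, 2, 25)
        pred = m.predict(np.column_stack([t, np.zeros_like(t)]))
        assert np.all(np.diff(pred) > 0)

    def test_row_order_invariance(self, rng):
        X = rng.normal(size=(40, 2))
        y = rng.gamma(3.0, np.exp(0.5 * X[:, 0]) / 3.0)
        perm = rng.permutation(40)
        a = TweedieGLMRegressor(power=1.4).fit(X, y)
        b = TweedieGLMRegressor(power=1.4).fit(X[perm], y[perm])
        assert a.intercept_ == pytest.approx(b.intercept_, rel=1e-8)
        assert a.coef_ == pytest.approx(b.coef_, rel=1e-8)

    def test_negative_targets_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            TweedieGLMRegressor(power=1.5).fit(X, np.array([1.0] * 9 + [-0.1]))
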