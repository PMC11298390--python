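"""The three regression families: piecewise polynomial, kernel ridge, Tweedie.

All three are scikit-learn style estimators (``fit`` / ``predict`` /
``get_params``) over a two-column feature matrix, here standardized
(temperature, pressure).  Each exposes the complexity count used by the AIC
filter: the number of free polynomial coefficients for the piecewise model,
the trace of the smoother matrix (effective degrees of freedom) for kernel
ridge, and the coefficient count plus one dispersion parameter for the
Tweedie GLM.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "PiecewisePolynomialRegressor",
    "RBFKernelRidgeRegressor",
    "TweedieGLMRegressor",
    "tweedie_unit_deviance",
    "polynomial_basis",
    "solve_kernel_ridge_dual",
]


def polynomial_basis(X: np.ndarray, degree: int) -> np.ndarray:
    """All monomials of total degree <= ``degree`` in the two columns of X.

    Column order: constant, then by total degree, x before y within a degree
    (1, x, y, x^2, xy, y^2, ...).
    """
    X = np.asarray(X, float)
    cols = []
    for d in range(degree + 1):
        for i in range(d, -1, -1):
            cols.append(X[:, 0] ** i * X[:, 1] ** (d - i))
    return np.column_stack(cols)


def _n_monomials(degree: int) -> int:
    return (degree + 1) * (degree + 2) // 2


def _leaf_rss(B: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, *_ = np.linalg.lstsq(B, y, rcond=None)
    resid = y - B @ coef
    return coef, float(resid @ resid)


class PiecewisePolynomialRegressor(RegressorMixin, BaseEstimator):
    """Piecewise polynomial regression on a CART-style partition.

    The (T, P) box is split greedily by axis-aligned cuts (midpoints between
    sorted unique training coordinates); at each step the cut that most
    decreases the penalized criterion

        RSS + penalty_weight * n_parameters

    is accepted, until no cut helps, ``max_segments`` leaves are reached, or
    a child would hold fewer points than its polynomial has coefficients.
    Each leaf then carries an independent ordinary-least-squares polynomial
    of total degree ``degree``; no continuity is imposed at boundaries.

    Parameters
    ----------
    degree : int, 1-3
        Polynomial total degree within each segment.
    max_segments : int
        Maximum number of leaves.
    penalty_weight : float
        Weight of the per-coefficient complexity penalty, in squared target
        units.

    Attributes
    ----------
    tree_ : dict
        Nested split/leaf structure (JSON-serializable).
    n_parameters_ : int
        Total free coefficients, ``n_leaves * n_monomials(degree)``.
    """

    def __init__(self, degree: int = 2, max_segments: int = 4, penalty_weight: float = 0.0):
        self.degree = degree
        self.max_segments = max_segments
        self.penalty_weight = penalty_weight

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_features=2)
        if X.shape[1] != 2:
            raise ValueError("expects exactly two features (temperature, pressure)")
        if self.degree not in (1, 2, 3):
            raise ValueError("degree must be 1, 2 or 3")
        if self.max_segments < 1:
            raise ValueError("max_segments must be >= 1")
        m = _n_monomials(self.degree)
        if len(y) < m:
            raise ValueError(
                f"{len(y)} rows cannot identify a degree-{self.degree} "
                f"polynomial ({m} coefficients); need at least {m} rows"
            )

        # leaves: list of (index array, coef, rss)
        # splits must beat this margin so float-level RSS noise on exactly
        # polynomial data never triggers a spurious cut
        improvement_floor = -1e-10 * float(np.sum((y - y.mean()) ** 2)) - 1e-300

        idx_all = np.arange(len(y))
        coef, rss = _leaf_rss(polynomial_basis(X[idx_all], self.degree), y[idx_all])
        leaves = [(idx_all, coef, rss)]
        # nodes mirror leaves structurally; leaves[i] lives at slot paths[i]
        tree: dict = {"leaf": 0}
        paths: list[tuple[dict, str | None]] = [(tree, None)]

        while len(leaves) < self.max_segments:
            best = None  # ((delta, axis, threshold, leaf_pos), split parts)
            for leaf_pos, (idx, _, leaf_rss_val) in enumerate(leaves):
                Xl = X[idx]
                for axis in (0, 1):
                    uniq = np.unique(Xl[:, axis])
                    for thr in (uniq[:-1] + uniq[1:]) / 2.0:
                        left = idx[Xl[:, axis] < thr]
                        right = idx[Xl[:, axis] >= thr]
                        if len(left) < m or len(right) < m:
                            continue
                        cl, rl = _leaf_rss(polynomial_basis(X[left], self.degree), y[left])
                        cr, rr = _leaf_rss(polynomial_basis(X[right], self.degree), y[right])
                        delta = (rl + rr - leaf_rss_val) + self.penalty_weight * m
                        # strict improvement; ties -> earlier axis, lower threshold
                        key = (delta, axis, float(thr), leaf_pos)
                        if best is None or key < best[0]:
                            best = (key, (left, cl, rl), (right, cr, rr))
            if best is None or best[0][0] >= improvement_floor:
                break
            (_, axis, thr, leaf_pos), left_leaf, right_leaf = best
            node, _ = paths[leaf_pos]
            node.clear()
            node["axis"] = axis
            node["threshold"] = thr
            node["left"] = {"leaf": None}
            node["right"] = {"leaf": None}
            leaves[leaf_pos] = left_leaf
            paths[leaf_pos] = (node["left"], None)
            leaves.append(right_leaf)
            paths.append((node["right"], None))

        self._leaf_coefs_ = [coef for _, coef, _ in leaves]
        for i, (node, _) in enumerate(paths):
            node["leaf"] = i
        self.tree_ = tree
        self.n_leaves_ = len(leaves)
        self.n_parameters_ = self.n_leaves_ * m
        self.train_rss_ = float(sum(r for *_, r in leaves))
        self.n_features_in_ = 2
        return self

    def _route(self, x: np.ndarray) -> int:
        node = self.tree_
        while "axis" in node:
            # boundary points go to the right/upper child (x >= threshold)
            node = node["right"] if x[node["axis"]] >= node["threshold"] else node["left"]
        return node["leaf"]

    def predict(self, X):
        check_is_fitted(self, "tree_")
        X = check_array(X)
        out = np.empty(len(X))
        for i, x in enumerate(X):
            coef = self._leaf_coefs_[self._route(x)]
            out[i] = polynomial_basis(x[None, :], self.degree)[0] @ coef
        return out

    def to_dict(self) -> dict:
        """JSON-serializable model state."""
        check_is_fitted(self, "tree_")
        return {
            "family": "PPR",
            "degree": self.degree,
            "tree": self.tree_,
            "leaf_coefs": [c.tolist() for c in self._leaf_coefs_],
        }


def solve_kernel_ridge_dual(K: np.ndarray, y: np.ndarray, ridge_weight: float) -> np.ndarray:
    """Dual coefficients alpha of kernel ridge: (K + ridge_weight*N*I) alpha = y.

    Works for any symmetric PSD Gram matrix (linear, RBF, ...); Cholesky
    with a plain solve fallback.
    """
    n = len(y)
    A = K + ridge_weight * n * np.eye(n)
    try:
        return scipy.linalg.cho_solve(scipy.linalg.cho_factor(A), y)
    except scipy.linalg.LinAlgError:
        return np.linalg.solve(A, y)


class RBFKernelRidgeRegressor(RegressorMixin, BaseEstimator):
    """Kernel ridge regression with a Gaussian kernel, solved in the dual.

    Minimizes (1/N) sum_i (f(x_i) - y_i)^2 + ridge_weight * ||f||_H^2 over
    the RKHS of k(x, x') = exp(-gamma ||x - x'||^2).  The representer
    theorem gives f(x) = sum_i alpha_i k(x_i, x) with

        (K + ridge_weight * N * I) alpha = y,

    solved by Cholesky factorization.  ``effective_dof_`` is the trace of
    the smoother matrix K (K + ridge_weight*N*I)^-1, the complexity count
    used for AIC.
    """

    def __init__(self, ridge_weight: float = 1e-4, gamma: float = 1.0):
        self.ridge_weight = ridge_weight
        self.gamma = gamma

    @staticmethod
    def _kernel(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
        sq = (
            np.sum(A**2, axis=1)[:, None]
            + np.sum(B**2, axis=1)[None, :]
            - 2.0 * A @ B.T
        )
        return np.exp(-gamma * np.maximum(sq, 0.0))

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if self.ridge_weight <= 0 or self.gamma <= 0:
            raise ValueError("ridge_weight and gamma must be > 0")
        n = len(y)
        K = self._kernel(X, X, self.gamma)
        alpha = solve_kernel_ridge_dual(K, y, self.ridge_weight)
        A = K + self.ridge_weight * n * np.eye(n)
        try:
            smoother = scipy.linalg.cho_solve(scipy.linalg.cho_factor(A), K)
        except scipy.linalg.LinAlgError:  # cannot happen for ridge_weight>0, guarded anyway
            smoother = np.linalg.solve(A, K)
        self.X_fit_ = X
        self.dual_coef_ = alpha
        self.effective_dof_ = float(np.trace(smoother))
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "dual_coef_")
        X = check_array(X)
        return self._kernel(X, self.X_fit_, self.gamma) @ self.dual_coef_

    def to_dict(self) -> dict:
        check_is_fitted(self, "dual_coef_")
        return {
            "family": "KRR",
            "ridge_weight": self.ridge_weight,
            "gamma": self.gamma,
            "X_fit": self.X_fit_.tolist(),
            "dual_coef": self.dual_coef_.tolist(),
        }


def tweedie_unit_deviance(y, u, p: float):
    """Tweedie unit deviance d(y, u; p) for power p in (1, 2].

    d = 2 [ y^(2-p)/((1-p)(2-p)) - y u^(1-p)/(1-p) + u^(2-p)/(2-p) ],
    with the gamma limit 2[(y-u)/u - ln(y/u)] at p = 2.  Nonnegative, zero
    iff y == u.  For p in (1, 2), y = 0 is allowed (point mass at zero);
    means u must be positive.
    """
    y = np.asarray(y, float)
    u = np.asarray(u, float)
    if not (1.0 < p <= 2.0):
        raise ValueError("power p must lie in (1, 2]")
    if np.any(u <= 0):
        raise ValueError("means must be > 0")
    if np.any(y < 0) or (p == 2.0 and np.any(y <= 0)):
        raise ValueError("targets must be >= 0 (> 0 for the gamma case p=2)")
    if p == 2.0:
        return 2.0 * ((y - u) / u - np.log(y / u))
    return 2.0 * (
        np.power(y, 2.0 - p) / ((1.0 - p) * (2.0 - p))
        - y * np.power(u, 1.0 - p) / (1.0 - p)
        + np.power(u, 2.0 - p) / (2.0 - p)
    )


class TweedieGLMRegressor(RegressorMixin, BaseEstimator):
    """Tweedie GLM with log link, fitted by IRLS quasi-likelihood.

    Models E[Y] = exp(b0 + x.b) with variance Var(Y) = dispersion * mean^power.
    The working weights of the iteratively reweighted least squares are
    (du/deta)^2 / V(u) = u^(2-power) under the log link; dispersion is the
    mean squared Pearson residual over (n - n_coefficients).  An optional
    ridge term stabilizes the working normal equations (intercept excluded).

    Attributes
    ----------
    intercept_, coef_ : fitted regression parameters on the linear predictor.
    power_ : the variance power actually used.
    dispersion_ : estimated dispersion phi.
    n_parameters_ : coefficient count plus one for the dispersion.
    """

    def __init__(self, power: float = 1.5, ridge: float = 0.0,
                 max_iter: int = 100, tol: float = 1e-10):
        self.power = power
        self.ridge = ridge
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if not (1.0 < self.power <= 2.0):
            raise ValueError("power must lie in (1, 2]")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")
        if np.any(y < 0) or np.count_nonzero(y > 0) < 2:
            raise ValueError("targets must be >= 0 with at least two positive values")
        n, d = X.shape
        Xd = np.column_stack([np.ones(n), X])
        pen = np.diag(np.r_[0.0, np.full(d, self.ridge)])  # never penalize the intercept

        u = np.full(n, y.mean()) if y.mean() > 0 else np.full(n, 1.0)
        u = (y + u) / 2.0
        u = np.maximum(u, 1e-300)
        beta = np.zeros(d + 1)
        trace = []
        for it in range(self.max_iter):
            eta = np.log(u)
            z = eta + (y - u) / u           # working response, log link
            w = np.power(u, 2.0 - self.power)
            if not (np.all(np.isfinite(w)) and np.all(np.isfinite(z))):
                raise RuntimeError(
                    f"IRLS diverged at iteration {it}: non-finite working "
                    f"quantities; trace={trace}"
                )
            WX = Xd * w[:, None]
            beta_new = np.linalg.solve(Xd.T @ WX + pen, WX.T @ z)
            u = np.exp(np.clip(Xd @ beta_new, -690.0, 690.0))
            u = np.maximum(u, 1e-300)
            change = np.max(np.abs(beta_new - beta)) / max(1.0, np.max(np.abs(beta_new)))
            trace.append(float(change))
            beta = beta_new
            if change < self.tol:
                break
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.power_ = self.power
        pearson = (y - u) / np.sqrt(np.power(u, self.power))
        dof = max(n - (d + 1), 1)
        self.dispersion_ = float(pearson @ pearson / dof)
        self.n_parameters_ = d + 2  # coefficients + dispersion
        self.n_iter_ = it + 1
        self.n_features_in_ = d
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return np.exp(self.intercept_ + X @ self.coef_)

    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "family": "TDR",
            "power": self.power,
            "ridge": self.ridge,
            "intercept": self.intercept_,
            "coef": self.coef_.tolist(),
            "dispersion": self.dispersion_,
        }
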