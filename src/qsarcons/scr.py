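"""Self-consistent regression: ridge fitting with significance-driven
backward variable elimination and leave-one-out Q2.

A single (Q)SAR model is a ridge-regularized least-squares fit in
standardized feature space in which the least significant variables
(|coefficient| / SE below a threshold) are eliminated one at a time, each
removal re-fit, until every retained variable is significant and the
leave-one-out Q2 stops improving. The regularization strength is chosen
once, on the full variable set, by maximizing Q2 over a small grid, and the
whole procedure is deterministic for fixed inputs.

Leave-one-out statistics use the exact closed form for linear smoothers,
``e_loo_i = e_i / (1 - h_ii)`` with h the hat-matrix diagonal of the fixed
(standardized, intercept-augmented) design; this equals the explicit
refit-n-times loop for ridge with fixed preprocessing.

Qualitative (SAR) models reuse the same fitter on class labels coded +1/-1
and threshold the continuous prediction at zero, so the qualitative and
quantitative branches share data, descriptors and algorithm.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, RegressorMixin

DEFAULT_ALPHA_GRID = (0.01, 0.1, 1.0, 10.0)


def _check_Xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per response value")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in X or y")
    return X, y


def _ridge_stats(A: np.ndarray, y: np.ndarray, alpha: float) -> dict:
    """Ridge fit on design A (first column = intercept, unpenalized).

    Returns coefficients, residuals, hat diagonal, R2, LOO Q2 and
    coefficient standard errors, all for the fixed design A.
    """
    n, p = A.shape
    G = A.T @ A
    pen = np.full(p, alpha)
    pen[0] = 0.0
    M = linalg.inv(G + np.diag(pen))
    beta = M @ (A.T @ y)
    fitted = A @ beta
    resid = y - fitted
    AM = A @ M
    h = np.einsum("ij,ij->i", AM, A)
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = float(resid @ resid)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    denom = np.clip(1.0 - h, 1e-12, None)
    press = float(np.sum((resid / denom) ** 2))
    q2 = 1.0 - press / tss if tss > 0 else 0.0
    df = max(n - float(h.sum()), 1.0)
    sigma2 = rss / df
    cov = sigma2 * (M @ G @ M)
    se = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
    return {"beta": beta, "r2": r2, "q2": q2, "se": se, "resid": resid, "h": h}


def loo_q2(X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Leave-one-out Q2 of a ridge fit on the standardized design of X.

    Q2 = 1 - PRESS/TSS via the closed-form hat-matrix identity; exact for
    ridge with the preprocessing held fixed.
    """
    X, y = _check_Xy(X, y)
    if len(y) < 3:
        raise ValueError("leave-one-out Q2 needs at least 3 samples")
    A = _standardized_design(X)[0]
    return _ridge_stats(A, y, alpha)["q2"]


def _standardized_design(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale
    return np.column_stack([np.ones(len(X)), Xs]), mean, scale


class SelfConsistentRegressor(BaseEstimator, RegressorMixin):
    """Ridge regression with iterative elimination of insignificant variables.

    Parameters
    ----------
    alpha : fixed ridge strength, or None to pick from `alpha_grid` by
        leave-one-out Q2 on the full variable set
    alpha_grid : candidate strengths (applied in standardized space)
    t_threshold : minimum |coefficient|/SE for a variable to be retained
    min_variables : elimination never goes below this many variables unless
        forced by significance

    Fitted attributes
    -----------------
    coef_ : coefficients in the original feature units (zeros for
        eliminated variables); intercept_ likewise
    selected_ : indices of retained variables
    alpha_ : ridge strength used
    r2_train_, q2_train_ : training R2 and leave-one-out Q2
    """

    def __init__(
        self,
        alpha: float | None = None,
        alpha_grid: tuple = DEFAULT_ALPHA_GRID,
        t_threshold: float = 2.0,
        min_variables: int = 1,
    ):
        self.alpha = alpha
        self.alpha_grid = alpha_grid
        self.t_threshold = t_threshold
        self.min_variables = min_variables

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        n, p = X.shape
        if n < 10:
            raise ValueError("self-consistent regression needs at least 10 samples")
        if p == 0 or not np.any(X.std(axis=0) > 0):
            raise ValueError("feature matrix has no informative columns")

        A_full, mean, scale = _standardized_design(X)
        # collapse exact duplicate standardized columns: they carry no extra
        # information and only destabilize the significance statistics
        _, unique_idx = np.unique(np.round(A_full[:, 1:], 12), axis=1, return_index=True)
        sel = np.sort(unique_idx)
        sel = sel[X.std(axis=0)[sel] > 0]

        if self.alpha is not None:
            alpha = float(self.alpha)
        else:
            A = A_full[:, np.r_[0, sel + 1]]
            alpha = max(
                self.alpha_grid,
                key=lambda a: _ridge_stats(A, y, a)["q2"],
            )
        self.alpha_ = alpha

        if np.std(y) == 0:
            # degenerate response: intercept-only model, R2 = 0 by definition
            self.selected_ = np.array([], dtype=int)
            self.coef_ = np.zeros(p)
            self.intercept_ = float(y[0]) if n else 0.0
            self.r2_train_ = 0.0
            self.q2_train_ = 0.0
            return self

        stats = None
        # phase 1: eliminate until every retained variable is significant
        while len(sel) > 0:
            A = A_full[:, np.r_[0, sel + 1]]
            stats = _ridge_stats(A, y, alpha)
            t = np.abs(stats["beta"][1:]) / stats["se"][1:]
            if len(sel) <= self.min_variables or t.min() >= self.t_threshold:
                break
            sel = np.delete(sel, int(np.argmin(t)))
        # phase 2: keep dropping the weakest variable while LOO Q2 improves
        while len(sel) > self.min_variables:
            A = A_full[:, np.r_[0, sel + 1]]
            stats = _ridge_stats(A, y, alpha)
            t = np.abs(stats["beta"][1:]) / stats["se"][1:]
            trial = np.delete(sel, int(np.argmin(t)))
            trial_stats = _ridge_stats(A_full[:, np.r_[0, trial + 1]], y, alpha)
            if trial_stats["q2"] > stats["q2"]:
                sel, stats = trial, trial_stats
            else:
                break

        if stats is None:  # no variables survived deduplication
            sel = np.array([], dtype=int)
            self.coef_ = np.zeros(p)
            self.intercept_ = float(y.mean())
            self.r2_train_ = 0.0
            self.q2_train_ = 0.0
            self.selected_ = sel
            return self

        beta = stats["beta"]
        coef_std = np.zeros(p)
        coef_std[sel] = beta[1:]
        self.coef_ = coef_std / scale
        self.intercept_ = float(beta[0] - np.sum(coef_std * mean / scale))
        self.selected_ = np.asarray(sel, dtype=int)
        self.r2_train_ = float(stats["r2"])
        self.q2_train_ = float(stats["q2"])
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_


def internal_validation(
    estimator,
    X: np.ndarray,
    y: np.ndarray,
    n_splits: int = 5,
    holdout: float = 0.2,
    seed: int = 0,
) -> float:
    """Mean external R2 over `n_splits` random holdout splits.

    Each split holds out `holdout` of the rows, refits a clone of the
    estimator on the rest and scores R2 (test-set mean reference) on the
    held-out rows. Splits are reproducible from the seed.
    """
    from sklearn.base import clone

    X, y = _check_Xy(X, y)
    n = len(y)
    if n < 10:
        raise ValueError("internal validation needs at least 10 samples")
    rng = np.random.default_rng(seed)
    scores = []
    n_test = max(1, int(round(holdout * n)))
    for _ in range(n_splits):
        perm = rng.permutation(n)
        test, train = perm[:n_test], perm[n_test:]
        est = clone(estimator).fit(X[train], y[train])
        pred = est.predict(X[test])
        tss = float(np.sum((y[test] - y[test].mean()) ** 2))
        rss = float(np.sum((y[test] - pred) ** 2))
        scores.append(1.0 - rss / tss if tss > 0 else 0.0)
    return float(np.mean(scores))
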