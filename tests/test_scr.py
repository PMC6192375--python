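"""Self-consistent regression: recovery, elimination, LOO identities."""

import numpy as np
import pytest

from qsarcons.scr import (
    SelfConsistentRegressor,
    _ridge_stats,
    _standardized_design,
    internal_validation,
    loo_q2,
)


def ridge_solve(A, y, alpha):
    pen = np.full(A.shape[1], alpha)
    pen[0] = 0.0
    return np.linalg.solve(A.T @ A + np.diag(pen), A.T @ y)


def loo_q2_explicit(X, y, alpha):
    """Independent oracle: refit n times on the fixed standardized design."""
    A, _, _ = _standardized_design(X)
    press = 0.0
    for i in range(len(y)):
        keep = np.arange(len(y)) != i
        beta = ridge_solve(A[keep], y[keep], alpha)
        press += (y[i] - A[i] @ beta) ** 2
    tss = np.sum((y - y.mean()) ** 2)
    return 1.0 - press / tss


class TestFit:
    def test_recovers_planted_linear_signal(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 11))
        y = 2.0 * X[:, 0] + 1.0
        est = SelfConsistentRegressor().fit(X, y)
        assert list(est.selected_) == [0]
        assert est.coef_[0] == pytest.approx(2.0, abs=1e-2)
        assert est.intercept_ == pytest.approx(1.0, abs=1e-2)
        assert est.r2_train_ > 0.999

    def test_constant_response_gives_intercept_only(self):
        rng = np.random.default_rng(1)
        est = SelfConsistentRegressor().fit(rng.normal(size=(20, 3)), np.full(20, 5.0))
        assert est.selected_.size == 0
        assert est.intercept_ == pytest.approx(5.0)
        assert est.r2_train_ == 0.0

    def test_pure_noise_fails_internal_validation(self):
        rng = np.random.default_rng(2)
        below = 0
        for rep in range(20):
            X = rng.normal(size=(60, 15))
            y = rng.normal(size=60)
            est = SelfConsistentRegressor(alpha=1.0)
            r2bar = internal_validation(est, X, y, seed=rep)
            below += r2bar < 0.5
        assert below == 20

    def test_input_validation(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 3))
        with pytest.raises(ValueError):
            SelfConsistentRegressor().fit(np.zeros((20, 3)), rng.normal(size=20))
        bad = X.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            SelfConsistentRegressor().fit(bad, rng.normal(size=20))
        with pytest.raises(ValueError):
            SelfConsistentRegressor().fit(X[:5], rng.normal(size=5))


class TestLooQ2:
    def test_perfect_linear_data(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 2))
        y = X @ [1.0, -2.0] + 3.0
        assert loo_q2(X, y, alpha=1e-8) == pytest.approx(1.0, abs=1e-6)

    def test_hat_matrix_equals_explicit_refit_loop(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n, p = rng.integers(15, 40), rng.integers(2, 8)
            X = rng.normal(size=(n, p))
            y = X @ rng.normal(size=p) + rng.normal(size=n)
            alpha = float(rng.uniform(0.01, 5.0))
            assert loo_q2(X, y, alpha) == pytest.approx(loo_q2_explicit(X, y, alpha), abs=1e-8)

    def test_shuffled_response_collapses_q2(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(80, 10))
        y = X @ np.linspace(1, 2, 10) + rng.normal(scale=0.1, size=80)
        assert loo_q2(X, y, 1.0) > 0.9
        shuffled = [loo_q2(X, rng.permutation(y), 1.0) for _ in range(5)]
        assert np.mean(shuffled) < 0.15

    def test_needs_three_samples(self):
        with pytest.raises(ValueError):
            loo_q2(np.ones((2, 1)), np.ones(2), 1.0)


class TestProperties:
    def test_scale_equivariance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 6))
        y = X @ rng.normal(size=6) + rng.normal(scale=0.5, size=40)
        a = SelfConsistentRegressor(alpha=1.0).fit(X, y)
        b = SelfConsistentRegressor(alpha=1.0).fit(X, 10.0 * y)
        assert b.coef_ == pytest.approx(10.0 * a.coef_, rel=1e-9)
        assert b.r2_train_ == pytest.approx(a.r2_train_, abs=1e-9)
        assert b.q2_train_ == pytest.approx(a.q2_train_, abs=1e-9)

    def test_duplicate_column_changes_nothing(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 5))
        y = X @ rng.normal(size=5) + rng.normal(scale=0.3, size=40)
        a = SelfConsistentRegressor(alpha=1.0).fit(X, y)
        Xdup = np.column_stack([X, X[:, 0]])
        b = SelfConsistentRegressor(alpha=1.0).fit(Xdup, y)
        assert b.predict(Xdup) == pytest.approx(a.predict(X), abs=1e-8)
        assert b.r2_train_ >= a.r2_train_ - 1e-8

    def test_q2_below_r2_on_training_data(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n, p = rng.integers(20, 50), rng.integers(2, 8)
            X = rng.normal(size=(n, p))
            y = X @ rng.normal(size=p) + rng.normal(size=n)
            est = SelfConsistentRegressor(alpha=1.0).fit(X, y)
            assert est.q2_train_ <= est.r2_train_ + 1e-9

    def test_determinism(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(30, 8))
        y = rng.normal(size=30)
        a = SelfConsistentRegressor().fit(X, y)
        b = SelfConsistentRegressor().fit(X, y)
        assert np.array_equal(a.coef_, b.coef_) and a.intercept_ == b.intercept_


class TestInternalValidation:
    def test_noiseless_linear_recovery(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(60, 4))
        y = X @ [1.0, 2.0, -1.0, 0.5]
        assert internal_validation(SelfConsistentRegressor(alpha=0.01), X, y, seed=0) > 0.99

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(40, 5))
        y = rng.normal(size=40)
        est = SelfConsistentRegressor(alpha=1.0)
        assert internal_validation(est, X, y, seed=3) == internal_validation(est, X, y, seed=3)

    def test_pure_noise_mean_r2_nonpositive(self):
        rng = np.random.default_rng(13)
        vals = [
            internal_validation(
                SelfConsistentRegressor(alpha=1.0), rng.normal(size=(50, 8)), rng.normal(size=50), seed=i
            )
            for i in range(10)
        ]
        assert np.mean(vals) <= 0.0
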