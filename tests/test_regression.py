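"""Elastic-net coordinate descent against closed-form oracles."""

import numpy as np
import pytest
from sklearn.linear_model import ElasticNet as SkElasticNet

from cuffbp.regression import (ElasticNetRegressor, ElasticNetRegressorCV,
                               cv_select, load_model, save_model)


@pytest.fixture(scope="module")
def random_problem():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(60, 6))
    beta = np.array([2.0, -1.0, 0.0, 0.5, 0.0, 3.0])
    y = X @ beta + 0.5 * rng.normal(size=60) + 10.0
    return X, y


class TestSolverCorrectness:
    def test_lambda_zero_is_ols_toy(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([0.0, 1.0, 2.0])
        m = ElasticNetRegressor(lam=0.0).fit(X, y)
        assert m.coef_[0] == pytest.approx(1.0, abs=1e-9)
        assert m.intercept_ == pytest.approx(0.0, abs=1e-9)

    def test_lambda_zero_is_ols_random(self, random_problem):
        X, y = random_problem
        m = ElasticNetRegressor(lam=0.0).fit(X, y)
        ols = np.linalg.lstsq(np.column_stack([X, np.ones(len(y))]), y,
                              rcond=None)[0]
        assert np.max(np.abs(m.coef_ - ols[:-1])) < 1e-6
        assert abs(m.intercept_ - ols[-1]) < 1e-6

    def test_ridge_matches_closed_form(self, random_problem):
        X, y = random_problem
        lam = 13.7
        m = ElasticNetRegressor(lam=lam, alpha=0.0).fit(X, y)
        Xs = (X - X.mean(0)) / X.std(0)
        yc = y - y.mean()
        closed = np.linalg.solve(Xs.T @ Xs + (lam / 2) * np.eye(X.shape[1]),
                                 Xs.T @ yc)
        assert np.max(np.abs(m.coef_std_ - closed)) < 1e-6

    def test_lasso_soft_threshold_single_predictor(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        y = 1.5 * x + 0.3 * rng.normal(size=200)
        lam = 40.0
        m = ElasticNetRegressor(lam=lam, alpha=1.0).fit(x.reshape(-1, 1), y)
        xs = (x - x.mean()) / x.std()
        rho = xs @ (y - y.mean())
        expected = np.sign(rho) * max(abs(rho) - lam / 2, 0.0) / len(y)
        assert m.coef_std_[0] == pytest.approx(expected, abs=1e-9)

    def test_matches_sklearn_elastic_net(self, random_problem):
        # independent solver cross-check via the penalty-scale mapping
        # lam_here = 2 * n * alpha_sklearn
        X, y = random_problem
        lam, alpha = 18.0, 0.6
        mine = ElasticNetRegressor(lam=lam, alpha=alpha).fit(X, y)
        Xs = (X - X.mean(0)) / X.std(0)
        ref = SkElasticNet(alpha=lam / (2 * len(y)), l1_ratio=alpha,
                           tol=1e-12, max_iter=200000).fit(Xs, y)
        assert np.max(np.abs(mine.coef_std_ - ref.coef_)) < 1e-6

    def test_huge_penalty_collapses_to_intercept(self, random_problem):
        X, y = random_problem
        m = ElasticNetRegressor(lam=1e9, alpha=0.7).fit(X, y)
        assert np.allclose(m.coef_, 0.0)
        assert m.intercept_ == pytest.approx(y.mean(), abs=1e-9)

    def test_objective_monotone_every_fit(self, random_problem):
        X, y = random_problem
        for lam, alpha in [(0.0, 0.5), (1.0, 1.0), (50.0, 0.0), (5.0, 0.3)]:
            m = ElasticNetRegressor(lam=lam, alpha=alpha).fit(X, y)
            path = np.asarray(m.objective_path_)
            assert np.all(np.diff(path) <= 1e-8 * max(1.0, path.max()))

    def test_nonfinite_inputs_rejected(self):
        X = np.array([[1.0], [np.nan]])
        with pytest.raises(ValueError):
            ElasticNetRegressor().fit(X, np.array([1.0, 2.0]))


class TestCoefficientPath:
    def test_shrinkage_toward_zero_on_orthonormal_design(self):
        rng = np.random.default_rng(2)
        q, _ = np.linalg.qr(rng.normal(size=(80, 4)))
        X = q * np.sqrt(80)  # standardized-ish orthogonal columns
        y = X @ np.array([3.0, -2.0, 1.0, 0.5]) + 0.1 * rng.normal(size=80)
        prev = None
        for lam in [0.0, 1.0, 10.0, 100.0, 1000.0, 1e4]:
            m = ElasticNetRegressor(lam=lam, alpha=1.0).fit(X, y)
            mags = np.abs(m.coef_std_)
            if prev is not None:
                assert np.all(mags <= prev + 1e-9)
            prev = mags
        assert np.allclose(prev, 0.0, atol=1e-8)

    def test_sign_recovery_for_strong_effects(self, random_problem):
        X, y = random_problem
        m = ElasticNetRegressor(lam=1.0, alpha=0.5).fit(X, y)
        assert np.sign(m.coef_[0]) == 1 and np.sign(m.coef_[1]) == -1
        assert np.sign(m.coef_[5]) == 1


class TestCrossValidation:
    def test_single_grid_point_returned(self, random_problem):
        X, y = random_problem
        lam, alpha, curve = cv_select(X, y, lambda_grid=[2.5], alpha_grid=[0.75],
                                      n_folds=5, seed=0)
        assert lam == 2.5 and alpha == 0.75 and len(curve) == 1

    def test_noise_target_prefers_heavy_penalty(self):
        zeroed = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(80, 6))
            y = rng.normal(size=80)
            m = ElasticNetRegressorCV(lambdas=np.logspace(-2, 4, 20),
                                      alphas=[0.5, 1.0], n_folds=5,
                                      seed=seed).fit(X, y)
            mags = np.abs(m.coef_std_)
            # all/near-all coefficients eliminated or heavily shrunk
            zeroed += (np.count_nonzero(mags > 1e-6) <= 2) or np.all(mags <= 0.2)
        assert zeroed >= 9

    def test_strong_signal_reaches_noise_floor(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 4))
        sigma = 0.5
        y = X @ np.array([2.0, -1.0, 1.5, 0.8]) + sigma * rng.normal(size=200)
        m = ElasticNetRegressorCV(lambdas=np.logspace(-3, 2, 20),
                                  alphas=[0.0, 0.5, 1.0], n_folds=5,
                                  seed=3).fit(X, y)
        assert m.cv_mse_ <= 1.2 * sigma ** 2

    def test_fold_seed_determinism(self, random_problem):
        X, y = random_problem
        a = ElasticNetRegressorCV(lambdas=[0.1, 1.0], alphas=[0.5],
                                  n_folds=4, seed=9).fit(X, y)
        b = ElasticNetRegressorCV(lambdas=[0.1, 1.0], alphas=[0.5],
                                  n_folds=4, seed=9).fit(X, y)
        assert a.cv_curve_ == b.cv_curve_


class TestPredictionAndVariance:
    def test_zero_coefficients_predict_intercept(self, random_problem):
        X, y = random_problem
        m = ElasticNetRegressor(lam=1e9).fit(X, y)
        assert np.allclose(m.predict(X), m.intercept_)

    def test_in_sample_mse_bounded_by_objective(self, random_problem):
        X, y = random_problem
        m = ElasticNetRegressor(lam=3.0, alpha=0.5).fit(X, y)
        mse = np.mean((y - m.predict(X)) ** 2)
        assert mse <= m.objective_path_[-1] / len(y) + 1e-9

    def test_wrong_width_rejected(self, random_problem):
        X, y = random_problem
        m = ElasticNetRegressor(lam=0.0).fit(X, y)
        with pytest.raises(ValueError):
            m.predict(X[:, :3])

    def test_perfect_fit_zero_residual_variance(self):
        X = np.arange(10, dtype=float).reshape(-1, 1)
        y = 3.0 * X.ravel() + 2.0
        m = ElasticNetRegressor(lam=0.0).fit(X, y)
        assert m.residual_variance(X, y) == pytest.approx(0.0, abs=1e-12)

    def test_known_sigma_recovered(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(500, 3))
        sigma2 = 4.0
        y = X @ np.array([1.0, 2.0, -1.0]) + np.sqrt(sigma2) * rng.normal(size=500)
        m = ElasticNetRegressor(lam=0.0).fit(X, y)
        assert m.residual_variance(X, y) == pytest.approx(sigma2, rel=0.2)

    def test_noise_predictor_barely_moves_estimate(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(500, 3))
        y = X @ np.array([1.0, 2.0, -1.0]) + 2.0 * rng.normal(size=500)
        base = ElasticNetRegressor(lam=0.0).fit(X, y).residual_variance(X, y)
        X2 = np.column_stack([X, rng.normal(size=500)])
        aug = ElasticNetRegressor(lam=0.0).fit(X2, y).residual_variance(X2, y)
        assert abs(aug - base) / base < 0.05

    def test_model_round_trip(self, tmp_path, random_problem):
        import pandas as pd
        X, y = random_problem
        m = ElasticNetRegressor(lam=1.0, alpha=0.5).fit(X, y)
        path = tmp_path / "model.json"
        names = [f"f{i}" for i in range(X.shape[1])]
        save_model(m, path, feature_names=names, target="sbp")
        loaded = load_model(path)
        frame = pd.DataFrame(X, columns=names)
        assert np.allclose(loaded.predict_frame(frame), m.predict(X), atol=1e-9)
        with pytest.raises(KeyError):
            loaded.predict_frame(frame.rename(columns={"f0": "oops"}))
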