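"""Penalized linear regression of SBP/DBP on selected features.

The model is ``y = X beta + eps`` fit by minimizing

    SSE + lam * alpha * sum|beta_j| + lam * (1 - alpha)/2 * sum beta_j^2

by cyclic coordinate descent with soft-thresholding.  ``alpha`` mixes
the lasso (alpha=1) and ridge (alpha=0) penalties on a single shared
scale ``lam``; ``lam=0`` recovers ordinary least squares.  Features
are standardized (zero mean, unit variance) and the target centered
inside the fit; coefficients are reported on both scales.  With
standardized columns the per-coordinate update is

    beta_j <- S(rho_j, lam*alpha/2) / (n + lam*(1-alpha)/2),

where ``rho_j`` is the partial residual correlation and ``S`` the
soft-threshold operator; the objective is asserted non-increasing
across sweeps on every fit.

Cross-validation selects (lam, alpha) by mean held-out MSE over a
seeded fold assignment; the full MSE-vs-lambda curve is retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ElasticNetRegressor",
    "ElasticNetRegressorCV",
    "fit_elastic_net",
    "cv_select",
    "predict",
    "residual_variance",
    "DEFAULT_LAMBDA_GRID",
    "DEFAULT_ALPHA_GRID",
]

DEFAULT_LAMBDA_GRID = np.logspace(-3, 3, 50)
DEFAULT_ALPHA_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)


def _soft_threshold(rho: float, gamma: float) -> float:
    if rho > gamma:
        return rho - gamma
    if rho < -gamma:
        return rho + gamma
    return 0.0


def _cd_kernel(G, c, yty, lam, alpha, beta, tol, max_sweeps):
    """Cyclic coordinate descent in covariance form.

    G = Xs^T Xs, c = Xs^T y on standardized columns; ``beta`` is
    updated in place.  Returns (objective path, converged flag).
    """
    p = c.shape[0]
    gamma = lam * alpha / 2.0
    ridge = lam * (1.0 - alpha) / 2.0
    q = G @ beta
    path = np.empty(max_sweeps + 1)
    pen = lam * alpha * np.abs(beta).sum() + ridge * (beta @ beta)
    path[0] = yty - 2.0 * (beta @ c) + beta @ q + pen
    n_done = 0
    converged = False
    for _s in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            gjj = G[j, j]
            if gjj <= 0.0:
                continue
            rho = c[j] - q[j] + gjj * beta[j]
            if rho > gamma:
                new = (rho - gamma) / (gjj + ridge)
            elif rho < -gamma:
                new = (rho + gamma) / (gjj + ridge)
            else:
                new = 0.0
            delta = new - beta[j]
            if delta != 0.0:
                beta[j] = new
                q += delta * G[:, j]
                if abs(delta) > max_delta:
                    max_delta = abs(delta)
        pen = lam * alpha * np.abs(beta).sum() + ridge * (beta @ beta)
        path[n_done + 1] = yty - 2.0 * (beta @ c) + beta @ q + pen
        n_done += 1
        if max_delta < tol:
            converged = True
            break
    return path[: n_done + 1], converged


try:  # compiled inner loop; the pure-Python kernel is the reference
    from numba import njit as _njit
    _cd_kernel = _njit(cache=False)(_cd_kernel)
except ImportError:  # pragma: no cover
    pass


class ElasticNetRegressor(RegressorMixin, BaseEstimator):
    """Elastic-net linear regression by cyclic coordinate descent.

    Parameters
    ----------
    lam : float, penalty scale (0 gives ordinary least squares).
    alpha : float in [0, 1], lasso/ridge mix (1 = lasso, 0 = ridge).
    tol : convergence threshold on the max coefficient change per sweep.
    max_sweeps : sweep budget; non-convergence warns and keeps the
        best iterate.

    Attributes (after fit)
    ----------------------
    coef_ : coefficients on the original feature scale.
    coef_std_ : coefficients on the standardized scale.
    intercept_ : original-scale intercept (mmHg for BP targets).
    objective_path_ : penalized objective per sweep (non-increasing).
    """

    def __init__(self, lam: float = 0.0, alpha: float = 0.5,
                 tol: float = 1e-7, max_sweeps: int = 10000):
        self.lam = lam
        self.alpha = alpha
        self.tol = tol
        self.max_sweeps = max_sweeps

    def fit(self, X, y, beta_init=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be 2-D with one row per target value")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in inputs")
        if not (0.0 <= self.alpha <= 1.0) or self.lam < 0:
            raise ValueError("need alpha in [0,1] and lam >= 0")
        n, p = X.shape
        if n < 2:
            raise ValueError("need at least two samples")

        self.x_mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.x_scale_ = np.where(sd > 0, sd, 1.0)
        Xs = (X - self.x_mean_) / self.x_scale_
        self.y_mean_ = float(y.mean())
        yc = y - self.y_mean_

        lam, alpha = float(self.lam), float(self.alpha)

        # warm start (e.g. along a lambda path) speeds convergence; the
        # solution is unchanged because the objective is convex
        if beta_init is not None and np.shape(beta_init) == (p,):
            beta = np.asarray(beta_init, dtype=float).copy()
        else:
            beta = np.zeros(p)

        G = Xs.T @ Xs  # constant columns standardize to zero -> G_jj = 0
        cvec = Xs.T @ yc
        yty = float(yc @ yc)
        path, converged = _cd_kernel(np.ascontiguousarray(G), cvec, yty,
                                     lam, alpha, beta, self.tol,
                                     self.max_sweeps)
        scale = max(1.0, float(np.abs(path).max()))
        if np.any(np.diff(path) > 1e-8 * scale):
            raise AssertionError("coordinate-descent objective increased")
        if not converged:
            import warnings
            warnings.warn("coordinate descent did not converge; using best iterate",
                          stacklevel=2)
        self.objective_path_ = path.tolist()
        self.n_sweeps_ = len(path) - 1
        self.coef_std_ = beta
        self.coef_ = beta / self.x_scale_
        self.intercept_ = self.y_mean_ - float(self.coef_ @ self.x_mean_)
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, got {X.shape[1]}")
        return X @ self.coef_ + self.intercept_

    def residual_variance(self, X, y) -> float:
        """Unbiased error-variance estimate SSE / (n - m), with m the
        count of nonzero coefficients plus one for the intercept."""
        check_is_fitted(self, "coef_")
        y = np.asarray(y, dtype=float).ravel()
        r = y - self.predict(X)
        m = int(np.count_nonzero(self.coef_)) + 1
        if y.size <= m:
            return float("nan")
        return float(r @ r / (y.size - m))

    def to_dict(self, feature_names=None) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "features": list(feature_names) if feature_names is not None else None,
            "lam": float(self.lam), "alpha": float(self.alpha),
            "coef": self.coef_.tolist(), "coef_std": self.coef_std_.tolist(),
            "intercept": float(self.intercept_),
            "x_mean": self.x_mean_.tolist(), "x_scale": self.x_scale_.tolist(),
            "y_mean": self.y_mean_,
        }


class ElasticNetRegressorCV(RegressorMixin, BaseEstimator):
    """Elastic net with (lam, alpha) chosen by K-fold cross-validation.

    ``cv_curve_`` holds one entry per grid point: (lam, alpha,
    mean CV-MSE, se), enough to draw the MSE-versus-lambda plot.
    """

    def __init__(self, lambdas=None, alphas=None, n_folds: int = 10,
                 seed: int = 0, tol: float = 1e-7, max_sweeps: int = 10000,
                 cv_tol: float = 1e-5, cv_max_sweeps: int = 2000):
        self.lambdas = lambdas
        self.alphas = alphas
        self.n_folds = n_folds
        self.seed = seed
        self.tol = tol
        self.max_sweeps = max_sweeps
        self.cv_tol = cv_tol
        self.cv_max_sweeps = cv_max_sweeps

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        lambdas = np.asarray(DEFAULT_LAMBDA_GRID if self.lambdas is None
                             else self.lambdas, dtype=float)
        alphas = np.asarray(DEFAULT_ALPHA_GRID if self.alphas is None
                            else self.alphas, dtype=float)
        if lambdas.size == 0 or alphas.size == 0:
            raise ValueError("empty grids")
        n_folds = min(self.n_folds, len(y))
        if n_folds < 2:
            raise ValueError("need at least two folds")
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=self.seed)
        splits = list(kf.split(X))
        if any(len(tr) < 2 for tr, _ in splits):
            raise ValueError("a training fold has fewer than two rows")

        # warm-started descending-lambda path per (alpha, fold)
        lam_path = np.sort(lambdas)[::-1]
        mse = {}
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore", UserWarning)
            for a in alphas:
                for fi, (tr, te) in enumerate(splits):
                    beta = None
                    for lam in lam_path:
                        m = ElasticNetRegressor(
                            lam=lam, alpha=a, tol=self.cv_tol,
                            max_sweeps=self.cv_max_sweeps).fit(X[tr], y[tr],
                                                               beta_init=beta)
                        beta = m.coef_std_
                        e = y[te] - m.predict(X[te])
                        mse.setdefault((float(lam), float(a)), []).append(
                            float(e @ e / e.size))
        curve = []
        best = None
        for a in alphas:
            for lam in lambdas:
                fold_mse = mse[(float(lam), float(a))]
                mean = float(np.mean(fold_mse))
                se = float(np.std(fold_mse, ddof=1) / np.sqrt(len(fold_mse))) \
                    if len(fold_mse) > 1 else 0.0
                curve.append((float(lam), float(a), mean, se))
                if best is None or mean < best[2]:
                    best = (float(lam), float(a), mean)
        self.cv_curve_ = curve
        self.lam_, self.alpha_ = best[0], best[1]
        self.cv_mse_ = best[2]
        self.estimator_ = ElasticNetRegressor(lam=self.lam_, alpha=self.alpha_,
                                              tol=self.tol,
                                              max_sweeps=self.max_sweeps).fit(X, y)
        for attr in ("coef_", "coef_std_", "intercept_", "x_mean_", "x_scale_",
                     "y_mean_", "n_features_in_"):
            setattr(self, attr, getattr(self.estimator_, attr))
        return self

    def predict(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict(X)


# ---------------------------------------------------------------------------
# thin functional wrappers


def fit_elastic_net(X, y, lam: float, alpha: float, **kw) -> ElasticNetRegressor:
    return ElasticNetRegressor(lam=lam, alpha=alpha, **kw).fit(X, y)


def cv_select(X, y, lambda_grid=None, alpha_grid=None, n_folds: int = 10,
              seed: int = 0):
    """Returns ``(best_lam, best_alpha, cv_curve)``."""
    m = ElasticNetRegressorCV(lambdas=lambda_grid, alphas=alpha_grid,
                              n_folds=n_folds, seed=seed).fit(X, y)
    return m.lam_, m.alpha_, m.cv_curve_


def predict(model: ElasticNetRegressor, X):
    return model.predict(X)


def residual_variance(model: ElasticNetRegressor, X, y) -> float:
    return model.residual_variance(X, y)


def save_model(model, path, feature_names=None, target: str = "") -> None:
    d = model.to_dict(feature_names) if hasattr(model, "to_dict") \
        else model.estimator_.to_dict(feature_names)
    d["target"] = target
    if hasattr(model, "cv_curve_"):
        d["cv_curve"] = model.cv_curve_
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1)


@dataclass
class LoadedModel:
    """Deserialized model usable for prediction on named columns."""

    features: list
    coef: np.ndarray
    intercept: float
    target: str = ""

    def predict_frame(self, frame):
        missing = [c for c in self.features if c not in frame.columns]
        if missing:
            raise KeyError(f"missing feature columns: {missing}")
        return frame[self.features].to_numpy(dtype=float) @ self.coef + self.intercept


def load_model(path) -> LoadedModel:
    with open(path) as fh:
        d = json.load(fh)
    return LoadedModel(features=d.get("features") or [],
                       coef=np.asarray(d["coef"], dtype=float),
                       intercept=float(d["intercept"]),
                       target=d.get("target", ""))
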