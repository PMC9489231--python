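"""Two-layer ensemble regression: five base learners fused by stacking or
Bayesian model averaging.

The base learners are ridge regression (RR), a radial-kernel support-vector
regressor (SVM), a random forest (RF), a Gaussian process (GPR) and
distance-weighted k-nearest neighbours (KNN).  Each produces out-of-fold
(OOF) predictions under a quantile-stratified 5-fold split of the training
set; the meta-learners are trained on those OOF predictions so no base
model ever scores a sample it was trained on.

Stacking fits ordinary least squares of the target on the five OOF columns
(plus intercept) via the pseudoinverse, which tolerates collinear base
predictions.  BMA fits a finite mixture of normals centred on the base
predictions,

    y_i ~ sum_m  w_m * Normal(f_im, sigma_m^2),

by expectation-maximisation; the mixture weights are the posterior model
probabilities and the BMA point prediction is the weight-averaged base
prediction.  At test time meta inputs are the full-training-set refits'
predictions (standard anti-leakage stacking protocol).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.compose import TransformedTargetRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.linear_model import RidgeCV
from sklearn.neighbors import KNeighborsRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

BASE_LEARNERS = ("RR", "SVM", "RF", "GPR", "KNN")


def make_base_learner(name: str, seed: int = 0, **overrides):
    """Default-configured base learner (inputs assumed standardized)."""
    if name == "RR":
        params = dict(alphas=(0.01, 0.1, 1.0, 10.0, 100.0))
        params.update(overrides)
        return RidgeCV(**params)
    if name == "SVM":
        params = dict(kernel="rbf", C=10.0, epsilon=0.1, gamma="scale")
        params.update(overrides)
        return TransformedTargetRegressor(regressor=SVR(**params),
                                          transformer=StandardScaler())
    if name == "RF":
        # classic regression-forest default: m = p/3 candidate features/split
        params = dict(n_estimators=500, max_features=1.0 / 3.0,
                      random_state=seed, n_jobs=1)
        params.update(overrides)
        return RandomForestRegressor(**params)
    if name == "GPR":
        kernel = overrides.pop("kernel", None) or (
            ConstantKernel(1.0, (1e-3, 1e3)) * RBF(1.0, (1e-2, 1e3))
            + WhiteKernel(1e-2, (1e-8, 1e2)))
        params = dict(kernel=kernel, normalize_y=True, random_state=seed)
        params.update(overrides)
        return GaussianProcessRegressor(**params)
    if name == "KNN":
        params = dict(n_neighbors=5, weights="distance")
        params.update(overrides)
        return KNeighborsRegressor(**params)
    raise ValueError(f"unknown base learner {name!r}")


def quantile_stratified_folds(y: np.ndarray, k: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Fold ids balancing the target distribution across folds.

    Samples are sorted by y (random tie-break), grouped in consecutive
    blocks of k, and fold labels are permuted within each block.
    """
    n = len(y)
    order = np.lexsort((rng.random(n), np.asarray(y)))
    folds = np.empty(n, dtype=int)
    for start in range(0, n, k):
        block = order[start:start + k]
        folds[block] = rng.permutation(k)[:len(block)]
    return folds


@dataclass
class FittedEnsembleBase:
    """Five base models refit on the full training set, plus their OOF
    prediction matrix."""

    models: dict[str, object]
    oof: np.ndarray                  # (n_samples, n_models)
    fold_assignment: np.ndarray      # (n_samples,), values in [0, k)
    learner_names: tuple[str, ...] = BASE_LEARNERS


def fit_base_learners(X: np.ndarray, y: np.ndarray, k: int = 5,
                      seed: int = 0,
                      learner_names: tuple[str, ...] = BASE_LEARNERS,
                      overrides: dict[str, dict] | None = None
                      ) -> FittedEnsembleBase:
    """Cross-fit the base learners and refit them on all training data.

    ``X`` must already be imputed and standardized with training
    statistics (see :class:`phenofuse.features.Preprocessor`).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} samples for {k}-fold "
                         "cross-fitting")
    if np.ptp(y) == 0:
        raise ValueError("target is constant; nothing to regress")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("X and y must be finite")
    overrides = overrides or {}
    rng = np.random.default_rng(seed)
    folds = quantile_stratified_folds(y, k, rng)
    oof = np.full((n, len(learner_names)), np.nan)
    for j, name in enumerate(learner_names):
        for f in range(k):
            tr = folds != f
            model = make_base_learner(name, seed=seed + 13 * f + j,
                                      **overrides.get(name, {}))
            model.fit(X[tr], y[tr])
            oof[~tr, j] = model.predict(X[~tr])
    models = {}
    for j, name in enumerate(learner_names):
        model = make_base_learner(name, seed=seed + j,
                                  **overrides.get(name, {}))
        model.fit(X, y)
        models[name] = model
    return FittedEnsembleBase(models=models, oof=oof,
                              fold_assignment=folds,
                              learner_names=tuple(learner_names))


@dataclass
class StackingModel:
    """Linear meta-learner y ~ intercept + coefficients . base predictions."""

    intercept: float
    coefficients: np.ndarray

    def predict(self, base_predictions: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(base_predictions) @ \
            self.coefficients


def fit_stacking_meta(oof: np.ndarray, y: np.ndarray) -> StackingModel:
    """Ordinary least squares of y on the OOF columns, via pseudoinverse."""
    oof = np.asarray(oof, dtype=float)
    y = np.asarray(y, dtype=float)
    design = np.column_stack([np.ones(len(y)), oof])
    beta = np.linalg.pinv(design) @ y
    return StackingModel(intercept=float(beta[0]), coefficients=beta[1:])


@dataclass
class BMAModel:
    """Normal-mixture posterior weights over base-model point forecasts."""

    weights: np.ndarray              # (n_models,), simplex
    sigmas: np.ndarray               # (n_models,), residual SDs
    log_likelihood: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False

    def predict(self, base_predictions: np.ndarray) -> np.ndarray:
        return np.asarray(base_predictions) @ self.weights


def fit_bma(oof: np.ndarray, y: np.ndarray, tol: float = 1e-6,
            max_iter: int = 1000, sigma_floor: float = 1e-6) -> BMAModel:
    """EM for the normal mixture over base forecasts.

    E-step: responsibilities z_im proportional to w_m phi(y_i; f_im,
    sigma_m^2).  M-step: w_m = mean_i z_im; sigma_m^2 = weighted residual
    variance, floored at ``sigma_floor``.  Initialisation: uniform weights,
    sigma_m = SD(y - f_m).  Stops when the log-likelihood gain drops below
    ``tol``; the log-likelihood trace is non-decreasing.
    """
    F = np.asarray(oof, dtype=float)
    y = np.asarray(y, dtype=float)
    if F.ndim == 1:
        F = F[:, None]
    if not (np.isfinite(F).all() and np.isfinite(y).all()):
        raise ValueError("BMA requires finite predictions and targets")
    n, m = F.shape
    resid = y[:, None] - F
    w = np.full(m, 1.0 / m)
    sig = np.maximum(resid.std(axis=0), sigma_floor)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step in log space for numerical safety
        logphi = (-0.5 * np.log(2 * np.pi) - np.log(sig)[None, :]
                  - 0.5 * (resid / sig[None, :]) ** 2)
        logpost = np.log(np.maximum(w, 1e-300))[None, :] + logphi
        norm = logsumexp(logpost, axis=1)
        ll = float(norm.sum())
        z = np.exp(logpost - norm[:, None])
        if trace and ll - trace[-1] < tol:
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
        # M-step
        zsum = z.sum(axis=0)
        w = zsum / n
        sig2 = (z * resid ** 2).sum(axis=0) / np.maximum(zsum, 1e-300)
        sig = np.maximum(np.sqrt(sig2), sigma_floor)
    w = np.clip(w, 0.0, None)
    w = w / w.sum()
    return BMAModel(weights=w, sigmas=sig, log_likelihood=trace,
                    n_iter=it, converged=converged)


def base_predictions(models: dict[str, object], X_new: np.ndarray,
                     learner_names: tuple[str, ...] = BASE_LEARNERS
                     ) -> np.ndarray:
    return np.column_stack([models[n].predict(np.asarray(X_new, dtype=float))
                            for n in learner_names])


def predict_ensemble(base: FittedEnsembleBase,
                     meta: StackingModel | BMAModel,
                     X_new: np.ndarray,
                     return_std: bool = False):
    """Meta-combined predictions on new (preprocessed) samples.

    With ``return_std`` the Gaussian-process learner's predictive standard
    deviation is returned alongside (per-sample uncertainty estimate).
    """
    preds = base_predictions(base.models, X_new, base.learner_names)
    if not np.isfinite(preds).all():
        raise ValueError("non-finite base predictions")
    combined = meta.predict(preds)
    if return_std:
        _, std = base.models["GPR"].predict(
            np.asarray(X_new, dtype=float), return_std=True)
        return combined, std
    return combined
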