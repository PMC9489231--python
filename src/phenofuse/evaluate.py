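"""Evaluation protocol, correlation screening and trait mapping.

The headline protocol is a repeated 75/25 random holdout: per repeat the
training part is preprocessed (median imputation + standardization fitted on
the training rows only), the five base learners are cross-fitted (5-fold,
quantile-stratified) inside the training part, the stacking and BMA
meta-learners are trained on the out-of-fold predictions, and R2 / RMSE are
scored on the held-out 25 %.  Reported numbers are means (and SDs) over the
repeats.

R2 is defined as 1 - SS_res / SS_tot on the validation samples (not a
squared correlation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping

from .ensemble import (BASE_LEARNERS, FittedEnsembleBase, base_predictions,
                       fit_base_learners, fit_bma, fit_stacking_meta)
from .features import Preprocessor, select_features
from .scene import FieldScene

ENSEMBLE_MODELS = ("Stacking", "BMA")
ALL_MODELS = BASE_LEARNERS + ENSEMBLE_MODELS
TRAITS = ("LAI", "FW", "DW")


def r_squared(y, yhat) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("y and yhat must share length >= 2")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("R2 undefined for a constant target")
    return 1.0 - float(((y - yhat) ** 2).sum()) / ss_tot


def rmse(y, yhat) -> float:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 1:
        raise ValueError("y and yhat must share length >= 1")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


@dataclass
class HoldoutResult:
    """Per-model mean/SD validation metrics over the repeats."""

    table: pd.DataFrame           # rows: model; columns: r2_mean, r2_sd, ...
    n_repeats: int
    train_frac: float

    def metric(self, model: str, name: str) -> float:
        return float(self.table.loc[model, name])


def _fit_on_training(X_tr: pd.DataFrame, y_tr: np.ndarray, k: int,
                     seed: int) -> tuple[Preprocessor, FittedEnsembleBase,
                                         object, object]:
    prep = Preprocessor().fit(X_tr)
    Z_tr = prep.transform(X_tr)
    base = fit_base_learners(Z_tr, y_tr, k=k, seed=seed)
    stack = fit_stacking_meta(base.oof, y_tr)
    bma = fit_bma(base.oof, y_tr)
    return prep, base, stack, bma


def repeated_holdout_evaluate(X: pd.DataFrame, y: np.ndarray,
                              train_frac: float = 0.75,
                              repeats: int = 100, k: int = 5,
                              seed: int = 0,
                              stratify: np.ndarray | None = None,
                              ) -> HoldoutResult:
    """Repeated random-split evaluation of all seven models.

    ``stratify`` (optional; e.g. growth stage labels) makes the 75/25 split
    proportional within each stratum; the default split is fully random.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 8 or len(X) != n:
        raise ValueError("need n >= 8 samples with matching X and y")
    rng = np.random.default_rng(seed)
    scores = {m: {"r2": [], "rmse": []} for m in ALL_MODELS}
    for rep in range(repeats):
        test = _holdout_mask(n, train_frac, rng, stratify)
        rep_seed = int(rng.integers(0, 2 ** 31 - 1))
        X_tr, y_tr = X.loc[~test], y[~test]
        prep, base, stack, bma = _fit_on_training(X_tr, y_tr, k, rep_seed)
        Z_te = prep.transform(X.loc[test])
        preds = base_predictions(base.models, Z_te, base.learner_names)
        columns = {m: preds[:, j] for j, m in enumerate(base.learner_names)}
        columns["Stacking"] = stack.predict(preds)
        columns["BMA"] = bma.predict(preds)
        y_te = y[test]
        for m, yhat in columns.items():
            scores[m]["r2"].append(r_squared(y_te, yhat))
            scores[m]["rmse"].append(rmse(y_te, yhat))
    rows = {m: {"r2_mean": float(np.mean(s["r2"])),
                "r2_sd": float(np.std(s["r2"], ddof=1)) if repeats > 1 else 0.0,
                "rmse_mean": float(np.mean(s["rmse"])),
                "rmse_sd": float(np.std(s["rmse"], ddof=1)) if repeats > 1
                else 0.0}
            for m, s in scores.items()}
    table = pd.DataFrame(rows).T.loc[list(ALL_MODELS)]
    return HoldoutResult(table=table, n_repeats=repeats,
                         train_frac=train_frac)


def _holdout_mask(n: int, train_frac: float, rng: np.random.Generator,
                  stratify: np.ndarray | None) -> np.ndarray:
    """Boolean mask of test samples (size ~ (1 - train_frac) * n)."""
    test = np.zeros(n, dtype=bool)
    if stratify is None:
        n_test = max(1, int(round(n * (1.0 - train_frac))))
        test[rng.choice(n, size=n_test, replace=False)] = True
        return test
    strata = np.asarray(stratify)
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        n_test = max(1, int(round(len(idx) * (1.0 - train_frac))))
        test[rng.choice(idx, size=n_test, replace=False)] = True
    return test


def evaluate_feature_sets(features: pd.DataFrame, traits: pd.DataFrame,
                          set_names: list[str], trait_names=TRAITS,
                          train_frac: float = 0.75, repeats: int = 100,
                          k: int = 5, seed: int = 0,
                          stratify_by_stage: bool = False) -> pd.DataFrame:
    """Tidy evaluation report: one row per (trait, feature set, model).

    ``features`` and ``traits`` must be aligned row-wise (same plot x stage
    order).  The output mirrors the usual report layout: feature sets as
    rows, models as columns, R2 and RMSE per cell (long form here; see
    :func:`report_wide` for the table shape).
    """
    if len(features) != len(traits):
        raise ValueError("features and traits tables must align row-wise")
    stratify = features["stage_das"].to_numpy() if stratify_by_stage else None
    records = []
    for t_i, trait in enumerate(trait_names):
        y = traits[trait].to_numpy(dtype=float)
        for s_i, set_name in enumerate(set_names):
            X = select_features(features, set_name)
            res = repeated_holdout_evaluate(
                X, y, train_frac=train_frac, repeats=repeats, k=k,
                seed=seed + 1000 * t_i + 10 * s_i, stratify=stratify)
            for model in ALL_MODELS:
                records.append({
                    "trait": trait, "feature_set": set_name, "model": model,
                    "n_variables": X.shape[1],
                    "R2": res.metric(model, "r2_mean"),
                    "R2_sd": res.metric(model, "r2_sd"),
                    "RMSE": res.metric(model, "rmse_mean"),
                    "RMSE_sd": res.metric(model, "rmse_sd"),
                    "n_repeats": repeats,
                })
    return pd.DataFrame(records)


def report_wide(report: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Pivot a tidy report into the feature-set x model table for one trait
    (rows: feature set x {R2, RMSE}; columns: models)."""
    sub = report[report["trait"] == trait]
    out = sub.pivot_table(index=["feature_set", "n_variables"],
                          columns="model", values=["R2", "RMSE"],
                          sort=False)
    return out.swaplevel(axis=1)[list(ALL_MODELS)]


def feature_trait_correlations(features: pd.DataFrame,
                               traits: pd.DataFrame,
                               min_samples: int = 3) -> pd.DataFrame:
    """Pearson r between every feature column and every trait column.

    Missing values are dropped pairwise (listwise per pair); zero-variance
    pairs and pairs with fewer than ``min_samples`` complete observations
    are recorded as NaN.
    """
    feat = features.drop(columns=[c for c in ("plot_id", "stage_das")
                                  if c in features.columns])
    out = pd.DataFrame(index=feat.columns, columns=traits.columns,
                       dtype=float)
    for t in traits.columns:
        tv = traits[t].to_numpy(dtype=float)
        for f in feat.columns:
            fv = feat[f].to_numpy(dtype=float)
            ok = np.isfinite(fv) & np.isfinite(tv)
            if ok.sum() < min_samples or np.ptp(fv[ok]) == 0 \
                    or np.ptp(tv[ok]) == 0:
                out.loc[f, t] = np.nan
                continue
            out.loc[f, t] = float(np.corrcoef(fv[ok], tv[ok])[0, 1])
    return out


def quantile_classes(values: np.ndarray, n_classes: int = 5) -> np.ndarray:
    """Quantile class labels 1..n_classes (equal counts for distinct values).

    Classes are delimited by the empirical quantiles of ``values``; exactly
    equal values always share a class, so a constant input collapses into a
    single class.
    """
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        return np.empty(0, dtype=int)
    edges = np.unique(np.quantile(v, np.arange(1, n_classes) / n_classes))
    return 1 + np.searchsorted(edges, v, side="left").astype(int)


def map_traits(scene: FieldScene, features: pd.DataFrame,
               trained: dict[str, tuple[Preprocessor, FittedEnsembleBase,
                                        object]],
               set_name: str = "RGB+MS", n_classes: int = 5,
               geojson_path: str | Path | None = None) -> pd.DataFrame:
    """Per-plot trait predictions with quantile class labels.

    ``trained`` maps trait name -> (preprocessor, fitted base,
    meta-learner).  Returns one row per (plot, stage) with a prediction and
    a 1..n_classes quantile class per trait; optionally writes a GeoJSON
    choropleth (one feature per plot x stage with trait attributes).
    """
    out = features[["plot_id", "stage_das"]].copy()
    X = select_features(features, set_name)
    complete = ~X.isna().all(axis=1)
    for trait, (prep, base, meta) in trained.items():
        pred = np.full(len(X), np.nan)
        if complete.any():
            Z = prep.transform(X.loc[complete])
            preds = base_predictions(base.models, Z, base.learner_names)
            pred[complete.to_numpy()] = meta.predict(preds)
        out[trait] = pred
        cls = np.full(len(X), -1)
        ok = np.isfinite(pred)
        if ok.any():
            cls[ok] = quantile_classes(pred[ok], n_classes)
        out[f"{trait}_class"] = cls
        out[f"{trait}_missing"] = ~ok
    if geojson_path is not None:
        _write_trait_geojson(scene, out, geojson_path)
    return out


def _write_trait_geojson(scene: FieldScene, table: pd.DataFrame,
                         path: str | Path) -> None:
    geoms = {p.plot_id: p.polygon for p in scene.plots}
    features = []
    for rec in table.to_dict("records"):
        poly = geoms.get(rec["plot_id"])
        if poly is None:
            continue
        props = {k: (None if isinstance(v, float) and not np.isfinite(v)
                     else v) for k, v in rec.items()}
        features.append({"type": "Feature", "properties": props,
                         "geometry": mapping(poly)})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
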