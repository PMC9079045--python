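"""Random-forest regression of pIC50 with cross-validated assessment.

Performance statistics follow common QSAR practice: R² and Q² are the squared
Pearson correlation between observed and predicted activity (on training,
pooled 10-fold out-of-fold, or external predictions) and RMSE is the root mean
squared error.  Q² in its 1 - SSres/SStot form is available via
``q2_form="press"``.  Feature importance is the forest's mean decrease in
impurity (Gini importance), normalized to sum to one; the Occam refit retrains
on the top-k ranked features only.
"""
from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold


class ModelingError(ValueError):
    pass


@dataclass(frozen=True)
class RFConfig:
    """Random-forest hyperparameters.

    ``max_features`` follows scikit-learn semantics: "sqrt", an int, or a
    float fraction of the feature count (1/3 approximates the regression
    default of p/3).
    """

    n_trees: int = 500
    max_features: str | int | float = "sqrt"
    min_samples_leaf: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ModelingError("n_trees must be >= 1")
        if self.min_samples_leaf < 1:
            raise ModelingError("min_samples_leaf must be >= 1")


DEFAULT_TUNING_GRID: dict[str, list] = {
    "n_trees": [100, 500],
    "max_features": ["sqrt", 1 / 3],
    "min_samples_leaf": [1, 5],
}


@dataclass
class ModelBundle:
    forest: RandomForestRegressor
    config: RFConfig
    feature_names: list[str]
    gini_importances: np.ndarray

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X, self.feature_names)
        return self.forest.predict(X)


@dataclass
class CVResult:
    q2_cv: float
    rmse_cv: float
    fold_table: pd.DataFrame
    oof_predictions: np.ndarray


@dataclass
class PerformanceReport:
    """Train / cross-validated / external metrics for one fitted model."""

    r2_train: float
    rmse_train: float
    q2_cv: float
    rmse_cv: float
    q2_ext: float | None = None
    rmse_ext: float | None = None

    @property
    def margin(self) -> float | None:
        """R²_train - Q²_ext, the chance-correlation margin."""
        if self.q2_ext is None:
            return None
        return self.r2_train - self.q2_ext

    def to_dict(self) -> dict:
        d = asdict(self)
        d["margin"] = self.margin
        return d


def _as_matrix(X, feature_names: Sequence[str] | None = None) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if feature_names is not None:
            missing = [f for f in feature_names if f not in X.columns]
            if missing:
                raise ModelingError(f"missing features: {missing}")
            X = X[list(feature_names)]
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def evaluate(y_obs, y_pred) -> tuple[float, float]:
    """(squared Pearson correlation, RMSE) of predictions vs observations."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape or y_obs.ndim != 1:
        raise ModelingError("y_obs and y_pred must be equal-length vectors")
    if y_obs.size < 3:
        raise ModelingError("need at least 3 observations")
    if np.ptp(y_obs) == 0 or np.ptp(y_pred) == 0:
        raise ModelingError("correlation undefined for constant input")
    r, _ = stats.pearsonr(y_obs, y_pred)
    rmse = float(np.sqrt(np.mean((y_obs - y_pred) ** 2)))
    return float(r * r), rmse


def q2_score(y_obs, y_pred, form: str = "pearson") -> float:
    """Q² of held-out predictions: squared Pearson r (default) or the
    1 - SSres/SStot predictive-residual form."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if form == "pearson":
        return evaluate(y_obs, y_pred)[0]
    if form == "press":
        ss_res = float(np.sum((y_obs - y_pred) ** 2))
        ss_tot = float(np.sum((y_obs - y_obs.mean()) ** 2))
        if ss_tot == 0:
            raise ModelingError("constant y_obs")
        return 1.0 - ss_res / ss_tot
    raise ModelingError(f"unknown q2 form {form!r}")


def train(X, y, config: RFConfig | None = None,
          feature_names: Sequence[str] | None = None) -> ModelBundle:
    """Fit a bootstrap random-forest regressor; deterministic given the seed."""
    if config is None:
        config = RFConfig()
    if feature_names is None:
        feature_names = (
            list(X.columns) if isinstance(X, pd.DataFrame)
            else [f"x{j}" for j in range(np.asarray(X).shape[1])]
        )
    Xm = _as_matrix(X, feature_names)
    y = np.asarray(y, dtype=float)
    if np.isnan(Xm).any() or np.isnan(y).any():
        raise ModelingError("NaN in training data")
    forest = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        min_samples_leaf=config.min_samples_leaf,
        bootstrap=True,
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(Xm, y)
    importances = forest.feature_importances_
    total = importances.sum()
    if total > 0:
        importances = importances / total
    return ModelBundle(forest, config, list(feature_names), importances)


def cross_validate(
    X, y, config: RFConfig | None = None, folds: int = 10,
    seed: int = 0, q2_form: str = "pearson",
) -> CVResult:
    """K-fold CV with pooled out-of-fold Q².

    Rows are partitioned once (shuffled with ``seed``); each fold is predicted
    by a forest trained on the remaining folds, so every row is held out
    exactly once and Q² is computed on the pooled held-out predictions.
    """
    if config is None:
        config = RFConfig()
    Xm = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if folds < 2:
        raise ModelingError("need at least 2 folds")
    if folds > len(y):
        raise ModelingError("more folds than rows")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.full(len(y), np.nan)
    rows = []
    for k, (tr, te) in enumerate(kf.split(Xm)):
        if len(te) < 2:
            raise ModelingError("fold with fewer than 2 rows")
        bundle = train(Xm[tr], y[tr], config)
        pred = bundle.forest.predict(Xm[te])
        oof[te] = pred
        rows.append({"fold": k, "n_test": len(te),
                     "rmse": float(np.sqrt(np.mean((y[te] - pred) ** 2)))})
    q2 = q2_score(y, oof, form=q2_form)
    rmse = float(np.sqrt(np.mean((y - oof) ** 2)))
    return CVResult(q2, rmse, pd.DataFrame(rows), oof)


def _mf_rank(mf, p: int) -> float:
    """Resolve a max_features rule to a feature count, for tie-breaking."""
    if mf == "sqrt":
        return math.sqrt(p)
    if isinstance(mf, float):
        return mf * p
    return float(mf)


def tune(
    X, y, grid: dict[str, list] | None = None, cv_folds: int = 10, seed: int = 0
) -> RFConfig:
    """Exhaustive grid search scored by k-fold CV Q².

    Ties break toward fewer trees, then smaller max_features, then smaller
    leaves, so the winner is deterministic.
    """
    if grid is None:
        grid = DEFAULT_TUNING_GRID
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ModelingError("tuning grid must be non-empty")
    p = _as_matrix(X).shape[1]
    keys = sorted(grid)
    best: tuple | None = None
    best_config: RFConfig | None = None
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        config = RFConfig(
            n_trees=params.get("n_trees", 500),
            max_features=params.get("max_features", "sqrt"),
            min_samples_leaf=params.get("min_samples_leaf", 1),
            seed=seed,
        )
        cv = cross_validate(X, y, config, folds=cv_folds, seed=seed)
        key = (-cv.q2_cv, config.n_trees, _mf_rank(config.max_features, p),
               config.min_samples_leaf)
        if best is None or key < best:
            best, best_config = key, config
    return best_config


def rank_features(bundle: ModelBundle, k: int = 20) -> list[tuple[str, float]]:
    """Top-k features by Gini importance, descending; ties by name order."""
    order = sorted(
        range(len(bundle.feature_names)),
        key=lambda j: (-bundle.gini_importances[j], bundle.feature_names[j]),
    )
    k = min(k, len(order))
    return [(bundle.feature_names[j], float(bundle.gini_importances[j]))
            for j in order[:k]]


def evaluate_model(
    bundle: ModelBundle,
    X_train, y_train,
    X_ext=None, y_ext=None,
    folds: int = 10, cv_seed: int = 0, q2_form: str = "pearson",
) -> PerformanceReport:
    """Full train / CV / external report for a fitted model's configuration."""
    y_train = np.asarray(y_train, dtype=float)
    pred_tr = bundle.predict(X_train)
    r2_tr, rmse_tr = evaluate(y_train, pred_tr)
    cv = cross_validate(
        _as_matrix(X_train, bundle.feature_names), y_train, bundle.config,
        folds=folds, seed=cv_seed, q2_form=q2_form,
    )
    q2_ext = rmse_ext = None
    if X_ext is not None and y_ext is not None:
        y_ext = np.asarray(y_ext, dtype=float)
        pred_ext = bundle.predict(X_ext)
        q2_ext = q2_score(y_ext, pred_ext, form=q2_form)
        rmse_ext = float(np.sqrt(np.mean((y_ext - pred_ext) ** 2)))
    return PerformanceReport(r2_tr, rmse_tr, cv.q2_cv, cv.rmse_cv, q2_ext, rmse_ext)


def refit_top_k(
    X_train, y_train, bundle: ModelBundle, k: int = 20,
    X_ext=None, y_ext=None, folds: int = 10, cv_seed: int = 0,
) -> tuple[ModelBundle, PerformanceReport]:
    """Retrain on the top-k Gini-ranked features and re-evaluate identically."""
    selected = {name for name, _ in rank_features(bundle, k)}
    # keep the original column order so k = |features| reproduces the full
    # model exactly (tree growth is sensitive to feature order)
    top = [f for f in bundle.feature_names if f in selected]
    X_train = _frame_like(X_train, bundle.feature_names)[top]
    bundle2 = train(X_train, y_train, bundle.config, feature_names=top)
    X_ext2 = _frame_like(X_ext, bundle.feature_names)[top] if X_ext is not None else None
    report = evaluate_model(
        bundle2, X_train, y_train, X_ext2, y_ext, folds=folds, cv_seed=cv_seed
    )
    return bundle2, report


def _frame_like(X, feature_names: Sequence[str]) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float), columns=list(feature_names))


def save_bundle_metadata(bundle: ModelBundle, path: str | Path) -> None:
    """Persist the portable part of a model: config, features, importances."""
    meta = {
        "config": asdict(bundle.config),
        "feature_names": bundle.feature_names,
        "gini_importances": [float(v) for v in bundle.gini_importances],
    }
    Path(path).write_text(json.dumps(meta, indent=2))
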