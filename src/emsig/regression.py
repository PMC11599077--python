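"""Regression benchmark for predicting vaccine-dose counts from factor scores.

A suite spanning the usual model families (linear/generalized-linear,
tree, instance-based, Bayesian, gradient boosting, ensembles, plus a mean
"dummy" baseline) is trained on a 70/30 respondent split; six metrics
(R^2, MAE, MSE, RMSE, RMSLE, MAPE) are reported on the held-out 30%, and a
10-fold cross-validated R^2 on the training split accompanies each row.
Dose is treated as a numeric target in 0..5.

Metric conventions (the dose outcome forces two choices):

* RMSLE uses log1p after clipping predictions at 0, since log1p requires
  nonnegative arguments.
* MAPE is undefined at dose 0, which is a large share of any realistic
  cohort; it is computed over respondents with dose >= 1 by default, with a
  symmetric variant (sMAPE) available.

Predictor rankings come from tree-ensemble impurity-based feature
importance and from Shapley values estimated in-package by Monte Carlo
permutation sampling over a background sample. Multi-seed refitting gives
a top-5 stability profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import KFold, cross_val_score, train_test_split

__all__ = [
    "regression_metrics",
    "build_model_suite",
    "fit_suite",
    "shapley_values",
    "rank_predictors",
    "PredictorRanking",
]


def regression_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    *,
    mape_min_target: float = 1.0,
    symmetric_mape: bool = False,
) -> dict[str, float]:
    """Six-metric evaluation of a prediction vector.

    ``mape_min_target`` restricts the MAPE denominator to targets at or
    above the threshold (dose >= 1 by default); ``symmetric_mape`` switches
    to sMAPE with denominator (|y| + |yhat|) / 2 over all respondents.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    resid = y_true - y_pred
    mae = float(np.abs(resid).mean())
    mse = float((resid**2).mean())
    rmse = float(np.sqrt(mse))
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else np.nan
    clipped = np.clip(y_pred, 0.0, None)
    rmsle = float(np.sqrt(((np.log1p(y_true) - np.log1p(clipped)) ** 2).mean()))
    if symmetric_mape:
        denom = (np.abs(y_true) + np.abs(y_pred)) / 2.0
        ok = denom > 0
        mape = float((np.abs(resid[ok]) / denom[ok]).mean())
    else:
        ok = y_true >= mape_min_target
        mape = (
            float((np.abs(resid[ok]) / y_true[ok]).mean()) if ok.any() else np.nan
        )
    return {"r2": r2, "mae": mae, "mse": mse, "rmse": rmse, "rmsle": rmsle, "mape": mape}


def build_model_suite(seed: int = 0, include_boosters: bool = True) -> dict:
    """Default model list mirroring the common benchmark families.

    lightgbm / xgboost entries are included only when importable; absence
    produces a logged warning rather than an error so the suite runs in
    leaner environments.
    """
    from sklearn.dummy import DummyRegressor
    from sklearn.ensemble import (
        AdaBoostRegressor,
        ExtraTreesRegressor,
        GradientBoostingRegressor,
        RandomForestRegressor,
    )
    from sklearn.linear_model import (
        BayesianRidge,
        ElasticNet,
        HuberRegressor,
        Lars,
        Lasso,
        LassoLars,
        LinearRegression,
        OrthogonalMatchingPursuit,
        PassiveAggressiveRegressor,
        Ridge,
    )
    from sklearn.neighbors import KNeighborsRegressor
    from sklearn.tree import DecisionTreeRegressor

    suite = {
        "Linear Regression": LinearRegression(),
        "Ridge Regression": Ridge(random_state=seed),
        "Lasso Regression": Lasso(random_state=seed),
        "Least Angle Regression": Lars(),
        "Lasso Least Angle Regression": LassoLars(),
        "Huber Regressor": HuberRegressor(),
        "Elastic Net": ElasticNet(random_state=seed),
        "Orthogonal Matching Pursuit": OrthogonalMatchingPursuit(),
        "Bayesian Ridge": BayesianRidge(),
        "Decision Tree Regressor": DecisionTreeRegressor(random_state=seed),
        "K Neighbors Regressor": KNeighborsRegressor(),
        "Gradient Boosting Regressor": GradientBoostingRegressor(random_state=seed),
        "Random Forest Regressor": RandomForestRegressor(random_state=seed),
        "Extra Trees Regressor": ExtraTreesRegressor(random_state=seed),
        "AdaBoost Regressor": AdaBoostRegressor(random_state=seed),
        "Dummy Regressor": DummyRegressor(strategy="mean"),
    }
    with warnings.catch_warnings():
        # sklearn 1.8 deprecates the class in favor of an SGD spelling;
        # keep the familiar benchmark name while it exists
        warnings.simplefilter("ignore", FutureWarning)
        suite["Passive Aggressive Regressor"] = PassiveAggressiveRegressor(
            random_state=seed
        )
    if include_boosters:
        try:
            from lightgbm import LGBMRegressor

            suite["Light Gradient Boosting Machine"] = LGBMRegressor(
                random_state=seed, verbose=-1
            )
        except ImportError:
            warnings.warn("lightgbm unavailable; skipping its suite entry")
        try:
            from xgboost import XGBRegressor

            suite["Extreme Gradient Boosting"] = XGBRegressor(
                random_state=seed, verbosity=0
            )
        except ImportError:
            warnings.warn("xgboost unavailable; skipping its suite entry")
    return suite


def fit_suite(
    scores: pd.DataFrame,
    dose: pd.Series,
    *,
    split_seed: int = 0,
    test_size: float = 0.3,
    cv_folds: int = 10,
    models: dict | None = None,
    mape_min_target: float = 1.0,
) -> pd.DataFrame:
    """Train every suite model on the 70% split and score the 30% test set.

    Returns a frame of models x metrics sorted by test R^2 (descending),
    with a ``cv_r2_mean`` column from k-fold cross-validation on the
    training split. Raises on a constant dose (R^2 undefined).
    """
    if len(scores) < 50:
        raise ValueError("regression benchmark needs at least 50 respondents")
    y = dose.to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("dose is constant; regression target degenerate")
    x = scores.to_numpy(dtype=float)
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=test_size, random_state=split_seed
    )
    models = build_model_suite(split_seed) if models is None else models
    rows = []
    for name, est in models.items():
        est = clone(est)
        cv_r2 = np.nan
        if cv_folds and cv_folds >= 2:
            kf = KFold(n_splits=cv_folds, shuffle=True, random_state=split_seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cv_r2 = float(
                    cross_val_score(clone(est), x_tr, y_tr, cv=kf, scoring="r2").mean()
                )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(x_tr, y_tr)
        metrics = regression_metrics(
            y_te, est.predict(x_te), mape_min_target=mape_min_target
        )
        rows.append({"model": name, **metrics, "cv_r2_mean": cv_r2})
    report = pd.DataFrame(rows).sort_values("r2", ascending=False)
    return report.reset_index(drop=True)


def shapley_values(
    predict_fn,
    x_explain: np.ndarray,
    x_background: np.ndarray,
    *,
    n_permutations: int = 30,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Monte Carlo permutation-sampling Shapley attributions.

    For each explained row, features are introduced in random order on top
    of background rows; each feature's attribution is its average marginal
    change in the model prediction (Strumbelj-Kononenko sampling of the
    exact Shapley value under the interventional feature-removal
    convention). Returns an (n_explain, n_features) matrix whose rows sum
    to f(x) - E_background[f], up to Monte Carlo error.
    """
    rng = np.random.default_rng() if rng is None else rng
    x_explain = np.asarray(x_explain, dtype=float)
    x_background = np.asarray(x_background, dtype=float)
    n, p = x_explain.shape
    phi = np.zeros((n, p))
    for _ in range(n_permutations):
        order = rng.permutation(p)
        bg = x_background[rng.integers(0, len(x_background), size=n)]
        current = bg.copy()
        prev = predict_fn(current)
        for j in order:
            current[:, j] = x_explain[:, j]
            nxt = predict_fn(current)
            phi[:, j] += nxt - prev
            prev = nxt
    return phi / n_permutations


@dataclass
class PredictorRanking:
    """Attribution-ranked factors with cross-seed top-5 stability."""

    method: str
    ranking: list[tuple[str, float]]
    seeds: list[int] = field(default_factory=list)
    top5_stability: dict[str, float] = field(default_factory=dict)

    @property
    def ordered_factors(self) -> list[str]:
        return [f for f, _ in self.ranking]

    def top(self, k: int = 5) -> list[str]:
        return self.ordered_factors[:k]


def _rank_once(
    model,
    scores: pd.DataFrame,
    dose: pd.Series,
    seed: int,
    *,
    n_explain: int,
    n_permutations: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit on a seed-resampled 70% split; return (importance, mean |shap|)."""
    rng = np.random.default_rng(seed)
    x = scores.to_numpy(dtype=float)
    y = dose.to_numpy(dtype=float)
    x_tr, _, y_tr, _ = train_test_split(x, y, test_size=0.3, random_state=seed)
    est = clone(model)
    if "random_state" in est.get_params():
        est.set_params(random_state=seed)
    est.fit(x_tr, y_tr)
    if not hasattr(est, "feature_importances_"):
        raise TypeError(
            "feature importance requires a fitted tree ensemble; use the "
            "Shapley ranking for other model classes"
        )
    importance = np.asarray(est.feature_importances_, dtype=float)
    take = min(n_explain, len(x_tr))
    explain = x_tr[rng.choice(len(x_tr), size=take, replace=False)]
    phi = shapley_values(
        est.predict, explain, x_tr, n_permutations=n_permutations, rng=rng
    )
    return importance, np.abs(phi).mean(axis=0)


def rank_predictors(
    model,
    scores: pd.DataFrame,
    dose: pd.Series,
    seeds: list[int] | None = None,
    *,
    n_explain: int = 100,
    n_permutations: int = 30,
) -> tuple[PredictorRanking, PredictorRanking]:
    """Feature-importance and Shapley rankings with seed sensitivity.

    The model is refit on a resampled split per seed; rankings use the
    attribution averaged over seeds, and ``top5_stability`` records how
    often each factor lands in a seed's top 5.
    """
    seeds = list(range(10)) if seeds is None else list(seeds)
    factor_ids = list(scores.columns)
    imp_rows, shap_rows = [], []
    for seed in seeds:
        imp, sv = _rank_once(
            model,
            scores,
            dose,
            seed,
            n_explain=n_explain,
            n_permutations=n_permutations,
        )
        imp_rows.append(imp)
        shap_rows.append(sv)

    def _build(rows: list[np.ndarray], method: str) -> PredictorRanking:
        arr = np.vstack(rows)
        mean_attr = arr.mean(axis=0)
        order = np.argsort(-mean_attr)
        ranking = [(factor_ids[j], float(mean_attr[j])) for j in order]
        top5_counts = np.zeros(len(factor_ids))
        for row in arr:
            top5_counts[np.argsort(-row)[:5]] += 1
        stability = {
            factor_ids[j]: float(top5_counts[j] / len(rows))
            for j in range(len(factor_ids))
        }
        return PredictorRanking(
            method=method, ranking=ranking, seeds=seeds, top5_stability=stability
        )

    return _build(imp_rows, "feature_importance"), _build(shap_rows, "shapley")
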