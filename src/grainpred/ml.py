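"""Machine-learning classifiers/regressors with inner-CV hyperparameter tuning.

The menu mirrors the study: logistic regression (unpenalized, deliberately
fragile when features approach sample size), RBF-kernel SVM/SVR, random
forest and XGBoost, each tuned by grid search with inner 5-fold CV on the
training set only (features are standardized inside each fold for the
scale-sensitive models, so no information leaks from validation folds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

from .metrics import accuracy, confusion_counts, pearson

CLASSIFIER_KINDS = ("logistic", "svm_rbf", "random_forest", "xgboost")
REGRESSOR_KINDS = ("svr_rbf", "rf_regress", "xgb_regress")


@dataclass
class ModelSpec:
    kind: str
    grid: dict = field(default_factory=dict)
    inner_folds: int = 5

    def __post_init__(self):
        if self.kind not in CLASSIFIER_KINDS + REGRESSOR_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if not self.grid:
            self.grid = default_grid(self.kind)

    @property
    def is_classifier(self) -> bool:
        return self.kind in CLASSIFIER_KINDS


def default_grid(kind: str) -> dict:
    """Documented default tuning grids (the study's were unreported)."""
    if kind in ("svm_rbf", "svr_rbf"):
        return {"C": [0.1, 1.0, 10.0, 100.0], "gamma_scale": [0.5, 1.0, 2.0]}
    if kind in ("random_forest", "rf_regress"):
        return {"n_estimators": [500], "max_features": ["sqrt", 0.333, 1.0]}
    if kind in ("xgboost", "xgb_regress"):
        return {"max_depth": [2, 4, 6], "learning_rate": [0.05, 0.1, 0.3],
                "n_estimators": [200]}
    return {"none": [None]}  # logistic: no tunables


def make_estimator(kind: str, params: dict, n_features: int, seed: int):
    """Instantiate a (pipeline-wrapped where scale matters) estimator."""
    params = dict(params)
    gamma_scale = params.pop("gamma_scale", None)
    gamma = gamma_scale / n_features if gamma_scale is not None else "scale"
    params.pop("none", None)
    if kind == "logistic":
        est = LogisticRegression(penalty=None, max_iter=500, solver="lbfgs")
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    if kind == "svm_rbf":
        est = SVC(kernel="rbf", gamma=gamma, probability=False, **params)
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    if kind == "svr_rbf":
        est = SVR(kernel="rbf", gamma=gamma, **params)
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    if kind == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if kind == "rf_regress":
        return RandomForestRegressor(random_state=seed, **params)
    if kind in ("xgboost", "xgb_regress"):
        from xgboost import XGBClassifier, XGBRegressor
        cls = XGBClassifier if kind == "xgboost" else XGBRegressor
        return cls(random_state=seed, n_jobs=1, verbosity=0,
                   eval_metric="logloss" if kind == "xgboost" else "rmse", **params)
    raise ValueError(kind)


def _grid_points(grid: dict):
    keys = list(grid)
    for combo in product(*(grid[k] for k in keys)):
        yield dict(zip(keys, combo))


def tune_fit(spec: ModelSpec, X, y, seed: int = 0):
    """Grid search by inner k-fold CV; refit the best setting on all data.

    Inner criterion: accuracy for classifiers, Pearson correlation for
    regressors. Ties keep the first grid point in iteration order.
    Returns (fitted estimator, chosen hyperparameters).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if spec.is_classifier and len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    points = list(_grid_points(spec.grid))
    if len(points) == 1:
        best = points[0]
    else:
        if spec.is_classifier:
            splitter = StratifiedKFold(n_splits=spec.inner_folds, shuffle=True,
                                       random_state=seed)
        else:
            splitter = KFold(n_splits=spec.inner_folds, shuffle=True,
                             random_state=seed)
        best, best_score = None, -np.inf
        for params in points:
            scores = []
            for tr, va in splitter.split(X, y if spec.is_classifier else None):
                est = make_estimator(spec.kind, params, X.shape[1], seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(X[tr], y[tr])
                pred = est.predict(X[va])
                if spec.is_classifier:
                    scores.append(accuracy(confusion_counts(y[va], pred)))
                else:
                    r = pearson(y[va], pred) if len(va) >= 3 else np.nan
                    scores.append(0.0 if np.isnan(r) else r)
            score = float(np.mean(scores))
            if score > best_score:
                best, best_score = params, score
    est = make_estimator(spec.kind, best, X.shape[1], seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    return est, best


def decision_scores(est, X) -> np.ndarray:
    """Continuous scores for ROC: predict_proba of the positive class when
    available, else decision_function, else raw predictions."""
    if hasattr(est, "predict_proba"):
        try:
            return np.asarray(est.predict_proba(X))[:, -1]
        except AttributeError:  # pipeline without proba
            pass
    if hasattr(est, "decision_function"):
        return np.asarray(est.decision_function(X))
    return np.asarray(est.predict(X), dtype=float)
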