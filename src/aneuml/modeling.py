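"""Gain/loss classifiers with cross-validated auROC / auPRC.

Two binary tasks are modeled per event resolution: a *gain* model (gained vs
neutral arms) and a *loss* model (lost vs neutral); the whole-chromosome
analogues are called *trisomy* and *monosomy*.  One-vs-rest variants keep
all instances (event vs everything else).  Five methods are supported:
logistic regression, gradient boosting, XGBoost, random forest, and bagging,
each evaluated by stratified k-fold cross-validation with the positive-class
prevalence as the no-skill precision baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.ensemble import (
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import RandomizedSearchCV, StratifiedKFold
from xgboost import XGBClassifier

__all__ = [
    "METHODS",
    "ModelSpec",
    "CVResult",
    "make_estimator",
    "assemble_task",
    "baseline_precision",
    "cross_validate",
    "tune_hyperparameters",
    "fit_model",
    "apply_pretrained",
]

METHODS = (
    "logistic_regression",
    "gradient_boosting",
    "xgboost",
    "random_forest",
    "bagging",
)

_POSITIVE_LABEL = {
    "gain": "gain",
    "loss": "loss",
    "trisomy": "gain",
    "monosomy": "loss",
}


@dataclass(frozen=True)
class ModelSpec:
    """A method name, optional hyperparameter overrides, and a seed."""

    method: str = "gradient_boosting"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")


@dataclass
class CVResult:
    """Cross-validated performance of one method on one task."""

    method: str
    task: str
    n_folds: int
    auroc: float
    auprc: float
    baseline: float
    fold_auroc: list[float] = field(default_factory=list)
    fold_auprc: list[float] = field(default_factory=list)


def make_estimator(spec: ModelSpec):
    """Instantiate the sklearn / XGBoost estimator for a spec.

    Tree methods use the common library defaults; only the seed is pinned.
    """
    hp = dict(spec.hyperparameters)
    seed = spec.seed
    if spec.method == "logistic_regression":
        hp.setdefault("max_iter", 2000)
        return LogisticRegression(random_state=seed, **hp)
    if spec.method == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **hp)
    if spec.method == "xgboost":
        hp.setdefault("eval_metric", "logloss")
        hp.setdefault("tree_method", "hist")
        hp.setdefault("n_jobs", 1)
        return XGBClassifier(random_state=seed, **hp)
    if spec.method == "random_forest":
        hp.setdefault("n_jobs", 1)
        return RandomForestClassifier(random_state=seed, **hp)
    if spec.method == "bagging":
        hp.setdefault("n_jobs", 1)
        return BaggingClassifier(random_state=seed, **hp)
    raise ValueError(spec.method)


def assemble_task(
    features: pd.DataFrame,
    labels: pd.Series,
    task: str,
    *,
    one_vs_rest: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Build (X, y) for a task.

    The default contrasts event instances against neutral ones (the other
    event's instances are dropped); ``one_vs_rest`` keeps all instances and
    contrasts the event against everything else.
    """
    positive = _POSITIVE_LABEL.get(task)
    if positive is None:
        raise ValueError(f"unknown task {task!r}")
    labels = labels.reindex(features.index)
    if labels.isna().any():
        raise ValueError("labels do not cover all feature rows")
    if one_vs_rest:
        keep = np.ones(len(features), dtype=bool)
    else:
        keep = (labels == positive) | (labels == "neutral")
    X = features.loc[keep]
    y = (labels[keep] == positive).astype(int).to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(f"task {task!r} has an empty class")
    return X, y


def baseline_precision(y) -> float:
    """Prevalence of the positive class: the precision of a no-skill
    classifier and hence the expected auPRC."""
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty label vector")
    if y.sum() == 0:
        raise ValueError("no positive instances")
    return float(y.mean())


def _scores(model, X) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, list(model.classes_).index(1)]
    return model.decision_function(X)


def cross_validate(
    spec: ModelSpec, X: pd.DataFrame, y: np.ndarray, k: int = 10,
    task: str = "gain",
) -> CVResult:
    """Stratified k-fold cross-validation; mean auROC and auPRC over folds.

    Fold assignment is seeded through the spec, so results are reproducible.
    Requires ``k`` at most the minority-class count (otherwise a fold would
    be single-class and the metrics undefined).
    """
    y = np.asarray(y)
    minority = min(int(y.sum()), int(len(y) - y.sum()))
    if k > minority:
        raise ValueError(f"k={k} exceeds minority-class count {minority}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=spec.seed)
    aurocs, auprcs = [], []
    for train, test in skf.split(X, y):
        model = make_estimator(spec)
        model.fit(X.iloc[train], y[train])
        s = _scores(model, X.iloc[test])
        aurocs.append(roc_auc_score(y[test], s))
        auprcs.append(average_precision_score(y[test], s))
    return CVResult(
        method=spec.method,
        task=task,
        n_folds=k,
        auroc=float(np.mean(aurocs)),
        auprc=float(np.mean(auprcs)),
        baseline=baseline_precision(y),
        fold_auroc=[float(v) for v in aurocs],
        fold_auprc=[float(v) for v in auprcs],
    )


_SEARCH_SPACES = {
    "logistic_regression": {
        "C": _stats.loguniform(1e-3, 1e3),
        "penalty": ["l2"],
    },
    "gradient_boosting": {
        "n_estimators": _stats.randint(50, 400),
        "learning_rate": _stats.loguniform(1e-2, 0.5),
        "max_depth": _stats.randint(2, 8),
        "subsample": _stats.uniform(0.5, 0.5),
    },
    "xgboost": {
        "n_estimators": _stats.randint(50, 400),
        "learning_rate": _stats.loguniform(1e-2, 0.5),
        "max_depth": _stats.randint(2, 8),
        "subsample": _stats.uniform(0.5, 0.5),
        "colsample_bytree": _stats.uniform(0.5, 0.5),
    },
    "random_forest": {
        "n_estimators": _stats.randint(50, 400),
        "max_depth": [None, 3, 5, 8, 12],
        "max_features": ["sqrt", "log2", None],
    },
    "bagging": {
        "n_estimators": _stats.randint(10, 100),
        "max_samples": _stats.uniform(0.5, 0.5),
        "max_features": _stats.uniform(0.5, 0.5),
    },
}


def tune_hyperparameters(
    spec: ModelSpec,
    X: pd.DataFrame,
    y: np.ndarray,
    *,
    n_iter: int = 200,
    k: int = 10,
    objective: str = "precision",
) -> tuple[ModelSpec, RandomizedSearchCV]:
    """Randomized hyperparameter search optimized for precision.

    Samples ``n_iter`` configurations from the method's search space and
    scores each by stratified k-fold cross-validation; returns the
    argmax-precision configuration as a new spec (deterministic given the
    spec's seed) plus the fitted search object.
    """
    space = _SEARCH_SPACES[spec.method]
    search = RandomizedSearchCV(
        make_estimator(spec),
        space,
        n_iter=n_iter,
        scoring=objective,
        cv=StratifiedKFold(n_splits=k, shuffle=True, random_state=spec.seed),
        random_state=spec.seed,
        n_jobs=1,
        error_score="raise",
    )
    search.fit(X, np.asarray(y))
    best = dict(spec.hyperparameters)
    best.update(search.best_params_)
    return ModelSpec(spec.method, best, spec.seed), search


def fit_model(spec: ModelSpec, X: pd.DataFrame, y: np.ndarray):
    """Fit one estimator on the full task data (for interpretation)."""
    model = make_estimator(spec)
    model.fit(X, np.asarray(y))
    return model


def apply_pretrained(
    model, X: pd.DataFrame, y: np.ndarray, task: str = "gain"
) -> CVResult:
    """Evaluate a tumor-trained model on another instance set (e.g. CCLs).

    The feature registry must match exactly; otherwise the differing columns
    are reported.
    """
    trained_cols = getattr(model, "feature_names_in_", None)
    if trained_cols is not None:
        diff = set(trained_cols) ^ set(X.columns)
        if diff:
            raise ValueError(f"feature registry mismatch: {sorted(diff)}")
        X = X[list(trained_cols)]
    y = np.asarray(y)
    s = _scores(model, X)
    return CVResult(
        method=type(model).__name__,
        task=task,
        n_folds=1,
        auroc=float(roc_auc_score(y, s)),
        auprc=float(average_precision_score(y, s)),
        baseline=baseline_precision(y),
        fold_auroc=[float(roc_auc_score(y, s))],
        fold_auprc=[float(average_precision_score(y, s))],
    )
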