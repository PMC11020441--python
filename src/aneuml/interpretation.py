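"""Model interpretation: Shapley attributions, directionality, drivers.

For tree ensembles the attributions are exact path-dependent TreeSHAP values
(XGBoost models use the library's native ``pred_contribs``; sklearn
ensembles use :mod:`aneuml.treeshap`).  For logistic regression the exact
linear Shapley decomposition on the margin scale is used.  In all cases the
per-instance attributions plus the base value reproduce the model output
(additivity), which the test suite asserts to 1e-6 for tree explainers.

Global importance is the mean absolute attribution per feature; the
*direction* of a feature records whether its top-50% values push the model
toward the event class or the neutral class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline

from . import treeshap

__all__ = [
    "ShapSummary",
    "DriverInstanceSet",
    "compute_shap",
    "feature_direction",
    "driver_instances",
    "driver_counts",
    "exclusion_robustness",
    "importance_barplot",
]

log = logging.getLogger(__name__)


@dataclass
class ShapSummary:
    """Per-instance per-feature attributions and derived global measures.

    ``values`` is instances x features (signed, in ``output_scale`` units);
    ``base_values`` + row sums of ``values`` equal ``model_output``.
    ``mean_abs`` is the global importance; ``ranking`` maps feature name to
    importance rank (1 = most important).
    """

    values: pd.DataFrame
    base_values: pd.Series
    model_output: pd.Series
    mean_abs: pd.Series
    ranking: pd.Series
    output_scale: str  # "margin" | "probability"

    def additivity_gap(self) -> float:
        """Max |base + sum(attributions) - model output| over instances."""
        recon = self.base_values.to_numpy() + self.values.to_numpy().sum(axis=1)
        return float(np.max(np.abs(recon - self.model_output.to_numpy())))


def _is_fitted(model) -> bool:
    from sklearn.exceptions import NotFittedError
    from sklearn.utils.validation import check_is_fitted

    try:
        check_is_fitted(model)
        return True
    except NotFittedError:
        return False


def _xgb_shap(model, X: pd.DataFrame):
    import xgboost as xgb

    booster = model.get_booster() if hasattr(model, "get_booster") else model
    dmat = xgb.DMatrix(X.to_numpy(dtype=np.float32),
                       feature_names=list(X.columns))
    contribs = booster.predict(dmat, pred_contribs=True)
    phi = contribs[:, :-1].astype(float)
    base = contribs[:, -1].astype(float)
    margin = booster.predict(dmat, output_margin=True).astype(float)
    return phi, base, margin, "margin"


def _gbm_shap(model: GradientBoostingClassifier, X: pd.DataFrame):
    arr = X.to_numpy(dtype=float)
    phi = np.zeros(arr.shape)
    base = 0.0
    tree_sum = np.zeros(arr.shape[0])
    lr = model.learning_rate
    for est in model.estimators_[:, 0]:
        t = treeshap.from_sklearn_tree(est.tree_)
        phi += lr * treeshap.tree_shap(t, arr)
        base += lr * treeshap.expected_value(t)
        tree_sum += lr * est.tree_.predict(arr.astype(np.float32)).ravel()
    margin = model.decision_function(X)
    init = margin - tree_sum  # constant prior log-odds of the init estimator
    base = base + float(np.mean(init))
    return phi, np.full(arr.shape[0], base), margin, "margin"


def _forest_shap(model, X: pd.DataFrame):
    """Mean over trees, on the class-1 probability scale."""
    arr = X.to_numpy(dtype=float)
    phi = np.zeros(arr.shape)
    base = 0.0
    class_one = list(model.classes_).index(1) if 1 in model.classes_ else 1
    for est in model.estimators_:
        tr = est.tree_
        counts = tr.value[:, 0, :]
        prob = counts[:, class_one] / counts.sum(axis=1)
        t = treeshap.from_sklearn_tree(tr, value=prob)
        phi += treeshap.tree_shap(t, arr)
        base += treeshap.expected_value(t)
    n_est = len(model.estimators_)
    phi /= n_est
    base /= n_est
    output = model.predict_proba(X)[:, class_one]
    return phi, np.full(arr.shape[0], base), output, "probability"


def _linear_shap(model: LogisticRegression, X: pd.DataFrame):
    arr = X.to_numpy(dtype=float)
    w = model.coef_.ravel()
    mu = arr.mean(axis=0)
    phi = (arr - mu) * w
    base = float(w @ mu + model.intercept_[0])
    margin = model.decision_function(X)
    return phi, np.full(arr.shape[0], base), margin, "margin"


def compute_shap(model, X: pd.DataFrame) -> ShapSummary:
    """Exact Shapley attributions for a fitted classifier on ``X``.

    Supports XGBoost (native TreeSHAP), sklearn gradient boosting, random
    forests and tree baggers (own path-dependent TreeSHAP), logistic
    regression (exact linear attributions), and a Pipeline whose last step is
    one of these (earlier steps must be per-feature transforms such as
    scalers).
    """
    if isinstance(model, Pipeline):
        *steps, (_, last) = model.steps
        Xt = X.copy()
        for _, tf in steps:
            Xt = pd.DataFrame(tf.transform(Xt), index=X.index, columns=X.columns)
        inner = compute_shap(last, Xt)
        return ShapSummary(
            values=inner.values.set_axis(X.index, axis=0),
            base_values=inner.base_values.set_axis(X.index),
            model_output=inner.model_output.set_axis(X.index),
            mean_abs=inner.mean_abs,
            ranking=inner.ranking,
            output_scale=inner.output_scale,
        )
    if not _is_fitted(model):
        raise ValueError("model must be fitted before interpretation")
    name = type(model).__name__
    if name.startswith("XGB") or name == "Booster":
        phi, base, out, scale = _xgb_shap(model, X)
    elif isinstance(model, GradientBoostingClassifier):
        phi, base, out, scale = _gbm_shap(model, X)
    elif isinstance(model, (RandomForestClassifier, BaggingClassifier)):
        phi, base, out, scale = _forest_shap(model, X)
    elif isinstance(model, LogisticRegression):
        phi, base, out, scale = _linear_shap(model, X)
    else:
        raise TypeError(f"no Shapley explainer for model type {name}")
    values = pd.DataFrame(phi, index=X.index, columns=X.columns)
    mean_abs = values.abs().mean(axis=0)
    order = mean_abs.sort_values(ascending=False, kind="mergesort")
    ranking = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    return ShapSummary(
        values=values,
        base_values=pd.Series(base, index=X.index),
        model_output=pd.Series(np.asarray(out, dtype=float), index=X.index),
        mean_abs=mean_abs,
        ranking=ranking.reindex(values.columns),
        output_scale=scale,
    )


def feature_direction(shap_values: pd.DataFrame, X: pd.DataFrame) -> pd.Series:
    """Directionality of each feature: "event" or "neutral".

    Instances are split at the feature's median value (ties at the median go
    to the lower half); the direction is "event" when the mean attribution of
    the top-50% instances is positive, "neutral" otherwise.  Zero-variance
    features are flagged "undefined".
    """
    out = {}
    for feat in shap_values.columns:
        x = X[feat].to_numpy(dtype=float)
        top = x > np.median(x)
        if not top.any():
            out[feat] = "undefined"
            continue
        mean_phi = shap_values[feat].to_numpy()[top].mean()
        out[feat] = "event" if mean_phi > 0 else "neutral"
    return pd.Series(out, name="direction")


@dataclass
class DriverInstanceSet:
    """Top-decile contributor instances of one feature."""

    feature: str
    positive_drivers: list
    negative_drivers: list


def driver_instances(
    summary: ShapSummary, top_k_features: int = 5, quantile: float = 0.10
) -> dict[str, DriverInstanceSet]:
    """Per top-ranked feature, the instances in the top decile of positive
    attributions (potential event drivers) and of negative attributions
    (potential neutrality drivers).  Decile sizes use the ceiling so driver
    sets are never empty when attributions of that sign exist."""
    top_feats = summary.ranking.sort_values().index[:top_k_features]
    out = {}
    for feat in top_feats:
        col = summary.values[feat]
        pos = col[col > 0].sort_values(ascending=False)
        neg = col[col < 0].sort_values()
        n_pos = int(np.ceil(quantile * len(pos))) if len(pos) else 0
        n_neg = int(np.ceil(quantile * len(neg))) if len(neg) else 0
        out[feat] = DriverInstanceSet(
            feature=feat,
            positive_drivers=list(pos.index[:n_pos]),
            negative_drivers=list(neg.index[:n_neg]),
        )
    return out


def driver_counts(drivers: dict[str, DriverInstanceSet], index) -> pd.Series:
    """Per instance, the number of top features for which it is a top
    contributor (in either decile)."""
    counts = pd.Series(0, index=index, dtype=int)
    for ds in drivers.values():
        for inst in (*ds.positive_drivers, *ds.negative_drivers):
            counts.loc[[inst]] += 1
    return counts


def exclusion_robustness(
    model,
    X: pd.DataFrame,
    y: np.ndarray,
    summary: ShapSummary | None = None,
    *,
    top_k_features: int = 5,
    threshold: int = 3,
) -> dict:
    """Re-fit without the strongest potential driver instances and compare
    feature rankings.

    Instances that are top contributors to at least ``threshold`` of the
    ``top_k_features`` most important features are excluded; the model is
    re-fitted on the remainder and re-interpreted.  Returns the excluded
    fraction, both rankings and the per-feature rank displacement.
    """
    if summary is None:
        summary = compute_shap(model, X)
    drivers = driver_instances(summary, top_k_features)
    counts = driver_counts(drivers, X.index)
    excluded = counts[counts >= threshold].index
    keep = ~X.index.isin(excluded)
    y = np.asarray(y)
    if len(np.unique(y[keep])) < 2:
        raise ValueError("exclusion would empty a class")
    refit = clone(model)
    refit.fit(X.loc[keep], y[keep])
    new_summary = compute_shap(refit, X.loc[keep])
    before = summary.ranking
    after = new_summary.ranking
    return {
        "excluded_fraction": float(len(excluded) / len(X)),
        "excluded_instances": list(excluded),
        "ranking_before": before,
        "ranking_after": after,
        "rank_displacement": (after - before).rename("rank_displacement"),
        "summary_after": new_summary,
    }


def importance_barplot(summary: ShapSummary, directions: pd.Series | None = None,
                       top_k: int = 10, ax=None):
    """Horizontal mean-|SHAP| bar plot, most important feature on top.

    When ``directions`` is given, event-directed features are annotated with
    a right arrow and neutral-directed ones with a left arrow.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * top_k + 1))
    top = summary.mean_abs.sort_values(ascending=False).head(top_k)[::-1]
    ax.barh(range(len(top)), top.to_numpy(), color="#4c72b0")
    labels = []
    for feat in top.index:
        arrow = ""
        if directions is not None and feat in directions.index:
            arrow = {"event": " →", "neutral": " ←"}.get(
                directions[feat], ""
            )
        labels.append(f"{feat}{arrow}")
    ax.set_yticks(range(len(top)), labels)
    ax.set_xlabel("mean |attribution|")
    return ax
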