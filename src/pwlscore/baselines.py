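"""Comparator models and threshold-based evaluation.

Two conventional baselines are fitted under the same stratified 5-fold CV
protocol as the point-wise linear model: logistic regression with
elastic-net regularization (penalty α(ρ‖β‖₁ + (1−ρ)/2‖β‖₂²), solved by
saga) and gradient-boosted trees on logistic loss (xgboost). Evaluation
reports AUC plus sensitivity/specificity at an operating point chosen
either by Youden's J or a fixed 0.5 probability cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from xgboost import XGBClassifier

from .errors import DegenerateLabelError, InvalidParameterError
from .pwl import CVResult, select_hyperparams_cv

__all__ = [
    "make_baseline",
    "fit_baseline",
    "evaluate_model",
    "EvalResult",
    "DEFAULT_GRIDS",
]

BASELINE_KINDS = ("elastic_net_lr", "gradient_boosting")

# Small default grids keep desk-scale runtime; alpha maps to sklearn's C=1/alpha.
DEFAULT_GRIDS = {
    "elastic_net_lr": {
        "C": [1.0 / a for a in (0.001, 0.01, 0.1, 1.0)],
        "l1_ratio": [0.2, 0.5, 0.8],
    },
    "gradient_boosting": {
        "max_depth": [2, 3],
        "n_estimators": [50, 200],
        "learning_rate": [0.05, 0.1],
    },
}


def make_baseline(kind: str, seed: int = 0):
    """An unfitted comparator estimator of the requested kind."""
    if kind == "elastic_net_lr":
        # l1_ratio + saga ⇒ elastic-net objective α(ρ‖β‖₁ + (1−ρ)/2‖β‖₂²)
        return LogisticRegression(
            solver="saga",
            l1_ratio=0.5,
            C=1.0,
            max_iter=10000,
            random_state=seed,
        )
    if kind == "gradient_boosting":
        return XGBClassifier(
            max_depth=3,
            n_estimators=100,
            learning_rate=0.1,
            objective="binary:logistic",
            eval_metric="logloss",
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
        )
    raise InvalidParameterError(f"unknown baseline kind {kind!r}; use {BASELINE_KINDS}")


@dataclass
class BaselineModel:
    kind: str
    cv: CVResult

    @property
    def estimator(self):
        return self.cv.best_estimator

    def predict_proba(self, X):
        return self.estimator.predict_proba(X)


def fit_baseline(
    kind: str, X, y, grid: dict | None = None, k: int = 5, seed: int = 0
) -> BaselineModel:
    """Grid-select and refit a comparator under stratified k-fold CV.

    Using the same (k, seed) as the point-wise linear CV reproduces the
    identical fold partition, so mean fold AUCs are head-to-head.
    """
    y_arr = np.asarray(y.to_numpy() if isinstance(y, pd.Series) else y)
    if np.unique(y_arr).size < 2:
        raise DegenerateLabelError("both outcome classes must be present")
    est = make_baseline(kind, seed=seed)
    cv = select_hyperparams_cv(
        est, X, y, grid if grid is not None else DEFAULT_GRIDS[kind], k=k, seed=seed
    )
    return BaselineModel(kind=kind, cv=cv)


@dataclass(frozen=True)
class EvalResult:
    auc: float
    sensitivity: float
    specificity: float
    threshold: float
    threshold_rule: str


def _scores_of(model, X) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return np.asarray(model.predict_proba(X))[:, 1]
    return np.asarray(model.decision_function(X))


def evaluate_model(model, X, y, threshold_rule: str = "youden") -> EvalResult:
    """AUC plus sensitivity/specificity at a chosen operating point.

    ``youden`` picks the ROC point maximizing sensitivity + specificity − 1;
    ``fixed-0.5`` cuts predicted probabilities at 0.5.
    """
    y_arr = np.asarray(y.to_numpy() if isinstance(y, pd.Series) else y)
    if np.unique(y_arr).size < 2:
        raise DegenerateLabelError("AUC undefined with a single class")
    scores = _scores_of(model, X)
    auc = float(roc_auc_score(y_arr, scores))
    if threshold_rule == "youden":
        fpr, tpr, thresholds = roc_curve(y_arr, scores)
        j = tpr - fpr
        thr = float(thresholds[int(np.argmax(j))])
        pred = scores >= thr
    elif threshold_rule == "fixed-0.5":
        thr = 0.5
        pred = scores >= thr
    else:
        raise InvalidParameterError(f"unknown threshold rule {threshold_rule!r}")
    pos = y_arr == np.unique(y_arr)[1]  # larger label = positive class
    sens = float(np.mean(pred[pos]))
    spec = float(np.mean(~pred[~pos]))
    return EvalResult(
        auc=auc,
        sensitivity=sens,
        specificity=spec,
        threshold=thr,
        threshold_rule=threshold_rule,
    )
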