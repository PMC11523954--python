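"""Sample-wise importance, feature extraction, and simple prediction scores.

From the per-sample weight vectors of the point-wise linear model, the
importance of feature i for sample j is |w_ji| (the magnitude of that
sample's own logistic coefficient; an alternative |w_ji·x_ji| mode is
available). Per sample, the top 10% of features by importance are "ranked";
a feature's importance score s_i is the fraction of samples ranking it, so
s_i = 0.1 means at least 10% of samples put the feature in their top decile.
Features with s_i ≥ 0.1 are extracted, each carrying the sign of its median
sample-wise weight over the model-building cohort, and the simple
prediction score of a sample is the signed sum of its extracted feature
values: S_j = Σ σ_i·x_ji on the preprocessed (±1 / z-normalized) scale.
Scores are stratified into quartile groups Q1 (lowest) … Q4 (highest).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DimensionError,
    EmptyModelError,
    InvalidParameterError,
    SchemaError,
)
from .pwl import SampleWiseWeights

__all__ = [
    "sample_importance",
    "importance_scores",
    "ImportanceReport",
    "build_importance_report",
    "extract_features",
    "SimpleScoreModel",
    "simple_score",
    "quartile_groups",
    "QuartileGrouping",
]

logger = logging.getLogger(__name__)

IMPORTANCE_CUTOFF = 0.1
TOP_FRACTION = 0.1


def sample_importance(
    weights: SampleWiseWeights | np.ndarray,
    mode: str = "abs_weight",
    X: np.ndarray | None = None,
) -> np.ndarray:
    """Per-sample, per-feature importance values (samples × features).

    ``abs_weight`` uses |w_ji|; ``abs_weight_times_value`` uses |w_ji·x_ji|
    (requires X). Intercepts never enter the ranking.
    """
    W = weights.weights if isinstance(weights, SampleWiseWeights) else np.asarray(weights)
    if not np.isfinite(W).all():
        raise InvalidParameterError("weights must be finite")
    if mode == "abs_weight":
        return np.abs(W)
    if mode == "abs_weight_times_value":
        if X is None:
            raise InvalidParameterError("mode 'abs_weight_times_value' needs X")
        X = np.asarray(X, float)
        if X.shape != W.shape:
            raise DimensionError("X and weights must share a shape")
        return np.abs(W * X)
    raise InvalidParameterError(f"unknown importance mode {mode!r}")


def top_k_of(d: int, top_fraction: float = TOP_FRACTION) -> int:
    """How many features count as a sample's 'top 10%': max(1, ceil(f·d))."""
    return max(1, math.ceil(top_fraction * d))


def importance_scores(
    sample_imp: np.ndarray, top_fraction: float = TOP_FRACTION
) -> np.ndarray:
    """Fraction of samples ranking each feature in their top decile.

    Per sample, features are ranked by importance descending with ties
    broken by stable feature order; exactly k = max(1, ceil(f·d)) features
    are ranked, so the scores conserve Σ_i s_i = k.
    """
    imp = np.asarray(sample_imp, float)
    if imp.ndim != 2 or imp.size == 0:
        raise DimensionError("need a non-empty samples × features matrix")
    n, d = imp.shape
    k = top_k_of(d, top_fraction)
    # stable argsort on -imp: descending importance, ties by feature order
    order = np.argsort(-imp, axis=1, kind="stable")
    ranked = np.zeros((n, d), dtype=bool)
    np.put_along_axis(ranked, order[:, :k], True, axis=1)
    return ranked.mean(axis=0)


@dataclass
class ImportanceReport:
    """Per-feature top-decile rate, median sample-wise weight, and sign."""

    table: pd.DataFrame  # feature, score, median_weight, sign, extracted
    top_fraction: float
    cutoff: float

    def __post_init__(self):
        s = self.table["score"]
        if ((s < 0) | (s > 1)).any():
            raise InvalidParameterError("importance scores must lie in [0, 1]")

    @property
    def extracted(self) -> pd.DataFrame:
        return self.table[self.table["extracted"]]

    def ranked_table(self) -> pd.DataFrame:
        """Extracted features by descending score, laid out like a published
        feature list (rank, parameter, score, median weight)."""
        out = self.extracted.sort_values("score", ascending=False).reset_index(drop=True)
        out.insert(0, "rank", np.arange(1, len(out) + 1))
        return out


def build_importance_report(
    weights: SampleWiseWeights,
    feature_names=None,
    top_fraction: float = TOP_FRACTION,
    cutoff: float = IMPORTANCE_CUTOFF,
    mode: str = "abs_weight",
    X: np.ndarray | None = None,
) -> ImportanceReport:
    """Scores + medians + signs from the model-building cohort's weights."""
    names = (
        list(feature_names)
        if feature_names is not None
        else (weights.feature_names or [f"x{i}" for i in range(weights.n_features)])
    )
    imp = sample_importance(weights, mode=mode, X=X)
    scores = importance_scores(imp, top_fraction)
    medians = np.median(weights.weights, axis=0)
    signs = np.sign(medians)
    table = pd.DataFrame(
        {
            "feature": names,
            "score": scores,
            "median_weight": medians,
            "sign": signs,
            "extracted": scores >= cutoff,
        }
    )
    return ImportanceReport(table=table, top_fraction=top_fraction, cutoff=cutoff)


@dataclass(frozen=True)
class SimpleScoreModel:
    """Signed feature list defining a simple prediction score."""

    features: tuple[str, ...]
    signs: tuple[int, ...]

    def __post_init__(self):
        if len(self.features) != len(self.signs):
            raise DimensionError("features and signs must align")
        if not set(self.signs) <= {-1, 1}:
            raise InvalidParameterError("signs must be +1 or -1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": self.features, "sign": self.signs})


def extract_features(
    report: ImportanceReport, cutoff: float | None = None
) -> SimpleScoreModel:
    """Keep features with score ≥ cutoff, signed by their median weight.

    Zero-median features carry no usable sign and are dropped with a
    warning; an empty result raises (the caller decides how to proceed).
    """
    cutoff = report.cutoff if cutoff is None else cutoff
    kept = report.table[report.table["score"] >= cutoff]
    zero_median = kept[kept["median_weight"] == 0]
    if len(zero_median):
        logger.warning(
            "dropping zero-median feature(s): %s", list(zero_median["feature"])
        )
        kept = kept[kept["median_weight"] != 0]
    if kept.empty:
        raise EmptyModelError(f"no feature reached importance score {cutoff}")
    return SimpleScoreModel(
        features=tuple(kept["feature"]),
        signs=tuple(int(s) for s in np.sign(kept["median_weight"])),
    )


def simple_score(model: SimpleScoreModel, features: pd.DataFrame) -> pd.Series:
    """S_j = Σ σ_i · x_ji over the model's features (preprocessed values)."""
    missing = [f for f in model.features if f not in features.columns]
    if missing:
        raise SchemaError(f"missing simple-score feature(s): {missing}")
    values = features[list(model.features)].to_numpy(float)
    scores = values @ np.asarray(model.signs, float)
    return pd.Series(scores, index=features.index, name="simple_score")


@dataclass
class QuartileGrouping:
    groups: pd.Series  # "Q1".."Q4" per sample, Q1 = lowest scores
    boundaries: pd.DataFrame  # per group: n, min score, max score


def quartile_groups(scores: pd.Series) -> QuartileGrouping:
    """Near-equal-size quartile groups of the pooled scores.

    Samples are ordered by score with ties broken by stable sample order,
    then cut into four contiguous blocks whose sizes differ by at most one
    (e.g. n = 112 → 28 per group).
    """
    s = pd.Series(scores)
    n = len(s)
    if n < 4:
        raise InvalidParameterError("need at least 4 samples for quartile groups")
    order = np.argsort(s.to_numpy(), kind="stable")
    sizes = [len(chunk) for chunk in np.array_split(np.arange(n), 4)]
    labels = np.empty(n, dtype=object)
    start = 0
    for q, size in enumerate(sizes, start=1):
        labels[order[start : start + size]] = f"Q{q}"
        start += size
    groups = pd.Series(labels, index=s.index, name="quartile")
    rows = []
    for q in ("Q1", "Q2", "Q3", "Q4"):
        vals = s[groups == q]
        rows.append(
            {"group": q, "n": len(vals), "min": vals.min(), "max": vals.max()}
        )
    return QuartileGrouping(groups=groups, boundaries=pd.DataFrame(rows))
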