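"""Feature coding frozen on the discovery cohort.

Binary variables are recoded to ±1, quantitative variables are z-normalized
with the discovery-cohort mean and sample SD, and missing entries become
exactly 0 *after* coding — so a missing quantitative value sits at the
discovery mean and a missing binary value halfway between the two classes.
SNP genotypes enter additively: the minor-allele count (0/1/2) is treated
as a quantitative variable and z-normalized like any lab value.

The fitted state is a plain serializable mapping, so the exact transform
applied to any later split is auditable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateFeatureError, InvalidParameterError, SchemaError

__all__ = ["ClinicalPreprocessor", "encode_genotypes", "fit_preprocess", "apply_preprocess"]


def encode_genotypes(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Validate minor-allele counts and return them as quantitative columns.

    Additive coding: the count itself is the feature value (heterozygotes
    weighted once, minor homozygotes twice); downstream z-normalization is
    the preprocessor's job.
    """
    arr = genotypes.to_numpy()
    if arr.size and not np.isin(arr[~pd.isna(arr)], [0, 1, 2]).all():
        bad = sorted(set(np.unique(arr[~pd.isna(arr)])) - {0, 1, 2})
        raise InvalidParameterError(f"genotype counts outside {{0,1,2}}: {bad}")
    return genotypes.astype(float)


class ClinicalPreprocessor(BaseEstimator, TransformerMixin):
    """±1 / z-score / missing→0 coding with discovery-frozen statistics.

    Parameters
    ----------
    binary_features : list of str, optional
        Columns to treat as binary. By default any column with exactly two
        distinct non-missing values is binary; everything else is
        quantitative.

    Attributes
    ----------
    coding_ : dict
        feature → {"type": "binary", "mapping": {low: -1, high: +1}} or
        {"type": "quantitative", "mean": μ, "sd": s} (sample SD, n−1).
    feature_names_in_ : ndarray of str
    """

    def __init__(self, binary_features=None):
        self.binary_features = binary_features

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            raise SchemaError("preprocessor expects a named-column DataFrame")
        declared = set(self.binary_features) if self.binary_features is not None else None
        coding: dict[str, dict] = {}
        degenerate = []
        for col in X.columns:
            values = X[col].dropna()
            uniques = np.sort(values.unique())
            is_binary = (
                col in declared if declared is not None else len(uniques) == 2
            )
            if is_binary:
                if len(uniques) != 2:
                    raise SchemaError(
                        f"binary feature {col!r} has {len(uniques)} distinct values"
                    )
                coding[col] = {
                    "type": "binary",
                    "mapping": {uniques[0]: -1.0, uniques[1]: 1.0},
                }
            else:
                if len(values) < 2:
                    raise SchemaError(
                        f"quantitative feature {col!r} needs >= 2 non-missing values"
                    )
                mu = float(values.mean())
                sd = float(values.std(ddof=1))
                if sd == 0.0:
                    degenerate.append(col)
                    continue
                coding[col] = {"type": "quantitative", "mean": mu, "sd": sd}
        if degenerate:
            raise DegenerateFeatureError(degenerate)
        self.coding_ = coding
        self.feature_names_in_ = np.asarray(list(X.columns), dtype=object)
        self.n_features_in_ = len(self.feature_names_in_)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "coding_"):
            raise SchemaError("preprocessor is not fitted")
        unseen = [c for c in X.columns if c not in self.coding_]
        if unseen:
            raise SchemaError(f"unseen feature name(s): {unseen}")
        missing = [c for c in self.coding_ if c not in X.columns]
        if missing:
            raise SchemaError(f"missing feature column(s): {missing}")
        out = pd.DataFrame(index=X.index, dtype=float)
        for col, spec in self.coding_.items():
            x = X[col]
            if spec["type"] == "binary":
                mapped = x.map(spec["mapping"])
                if (x.notna() & mapped.isna()).any():
                    bad = sorted(x[x.notna() & mapped.isna()].unique())
                    raise SchemaError(f"unmapped category in {col!r}: {bad}")
                out[col] = mapped
            else:
                out[col] = (x - spec["mean"]) / spec["sd"]
            out[col] = out[col].fillna(0.0)  # missing → 0 after coding
        if not np.isfinite(out.to_numpy()).all():
            raise InvalidParameterError("non-finite values after preprocessing")
        return out

    def get_feature_names_out(self, input_features=None):
        return np.asarray(list(self.coding_), dtype=object)

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            col: {
                **{k: v for k, v in spec.items() if k != "mapping"},
                **(
                    {"mapping": {str(k): v for k, v in spec["mapping"].items()}}
                    if spec["type"] == "binary"
                    else {}
                ),
            }
            for col, spec in self.coding_.items()
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, doc: dict) -> "ClinicalPreprocessor":
        pre = cls()
        coding = {}
        for col, spec in doc.items():
            if spec["type"] == "binary":
                coding[col] = {
                    "type": "binary",
                    "mapping": {float(k): v for k, v in spec["mapping"].items()},
                }
            else:
                coding[col] = dict(spec)
        pre.coding_ = coding
        pre.feature_names_in_ = np.asarray(list(coding), dtype=object)
        pre.n_features_in_ = len(coding)
        return pre

    @classmethod
    def load(cls, path: str | Path) -> "ClinicalPreprocessor":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_preprocess(discovery: pd.DataFrame, binary_features=None) -> ClinicalPreprocessor:
    """Fit the ±1 / z-score coding on the discovery cohort only."""
    return ClinicalPreprocessor(binary_features=binary_features).fit(discovery)


def apply_preprocess(state: ClinicalPreprocessor, table: pd.DataFrame) -> pd.DataFrame:
    """Apply a discovery-frozen transform to any split."""
    return state.transform(table)
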