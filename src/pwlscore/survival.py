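"""Outcome evaluation: Kaplan–Meier, log-rank, Harrell's C, quartile tables.

Time-to-event endpoints (PFS/CSS/OS) are summarized per score-quartile
group with the product-limit estimator and compared by the k-group
log-rank test; discrimination of a continuous score is measured by
Harrell's concordance index. Simple prediction scores are oriented
"higher = responder = better prognosis", so the risk entering the C-index
is the negated score. Quartile × response association uses the chi-square
test without continuity correction (df = (r−1)(c−1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index
from scipy import stats

from .errors import InvalidParameterError, UndefinedTestError

__all__ = [
    "km_estimate",
    "logrank_test",
    "harrell_c",
    "quartile_response_table",
    "LogrankResult",
    "ContingencyResult",
]


def _check_endpoint(time, event):
    time = np.asarray(time, float)
    event = np.asarray(event)
    if time.shape != event.shape or time.ndim != 1:
        raise InvalidParameterError("time and event must be parallel 1-d arrays")
    if (time < 0).any():
        raise InvalidParameterError("times must be non-negative")
    if not np.isin(event, [0, 1]).all():
        raise InvalidParameterError("event flags must be 0/1")
    return time, event.astype(int)


def km_estimate(time, event, groups=None) -> dict[str, pd.DataFrame]:
    """Product-limit survival curves, one step table per group.

    Each table has columns (time, survival, at_risk); survival is
    right-continuous, non-increasing, and starts at S(0) = 1. With
    ``groups=None`` a single curve keyed ``"all"`` is returned.
    """
    time, event = _check_endpoint(time, event)
    if groups is None:
        groups = np.full(time.shape, "all")
    groups = np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        mask = groups == g
        if not mask.any():
            raise InvalidParameterError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        sf = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"].reindex(sf.index).bfill().ffill()
        out[g] = pd.DataFrame(
            {
                "time": sf.index.to_numpy(float),
                "survival": sf.iloc[:, 0].to_numpy(float),
                "at_risk": at_risk.to_numpy(float),
            }
        ).reset_index(drop=True)
    return out


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    df: int
    p_value: float


def logrank_test(time, event, groups) -> LogrankResult:
    """k-group log-rank test; chi-square with k−1 df under the null."""
    time, event = _check_endpoint(time, event)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise InvalidParameterError("need at least 2 groups")
    if event.sum() == 0:
        raise UndefinedTestError("log-rank test undefined with no events")
    res = multivariate_logrank_test(time, groups, event)
    return LogrankResult(
        statistic=float(res.test_statistic),
        df=len(levels) - 1,
        p_value=float(res.p_value),
    )


def harrell_c(time, event, risk_scores, higher_score_better_prognosis: bool = True):
    """Harrell's concordance index of a score against a survival endpoint.

    Pairs are comparable when the earlier time is an event; a pair is
    concordant when the higher-risk sample fails first, and tied scores
    count ½. With the default orientation a *high* score means *good*
    prognosis (the responder convention), so risk = −score internally and
    C > 0.5 means the score orders survival correctly.
    """
    time, event = _check_endpoint(time, event)
    scores = np.asarray(risk_scores, float)
    if scores.shape != time.shape:
        raise InvalidParameterError("scores must align with times")
    if event.sum() == 0:
        raise UndefinedTestError("no comparable pairs: all observations censored")
    # lifelines expects predictions oriented 'higher = longer survival'
    predicted = scores if higher_score_better_prognosis else -scores
    return float(concordance_index(time, predicted, event))


@dataclass
class ContingencyResult:
    observed: pd.DataFrame  # groups × response counts
    statistic: float
    df: int
    p_value: float
    correct_fractions: pd.Series  # per group, fraction in its expected class
    q1_vs_q4: tuple[float, int, float] | None  # 2×2 collapse (stat, df, p)
    low_expected_warning: bool


def quartile_response_table(groups, responder) -> ContingencyResult:
    """Quartile × responder contingency with chi-square (no continuity corr.).

    Also reports per-group "correct prediction" fractions under the
    convention that low-score groups (Q1, Q2) are expected non-responders
    and high-score groups (Q3, Q4) responders, plus a Q1-vs-Q4 2×2 test
    when both groups are present.
    """
    groups = pd.Series(np.asarray(groups, dtype=object), name="group")
    resp = pd.Series(np.asarray(responder, dtype=int), name="responder")
    if resp.isna().any():
        raise InvalidParameterError("responder label must be defined for all samples")
    observed = pd.crosstab(groups, resp).reindex(
        sorted(groups.unique()), fill_value=0
    )
    chi2, p, df, expected = stats.chi2_contingency(observed, correction=False)
    fractions = {}
    for g in observed.index:
        total = observed.loc[g].sum()
        expect_responder = g in ("Q3", "Q4")
        correct = observed.loc[g].get(1 if expect_responder else 0, 0)
        fractions[g] = correct / total if total else np.nan
    q1q4 = None
    if {"Q1", "Q4"} <= set(observed.index):
        sub = observed.loc[["Q1", "Q4"]]
        if (sub.sum(axis=0) > 0).all():
            c2, p2, df2, _ = stats.chi2_contingency(sub, correction=False)
            q1q4 = (float(c2), int(df2), float(p2))
    return ContingencyResult(
        observed=observed,
        statistic=float(chi2),
        df=int(df),
        p_value=float(p),
        correct_fractions=pd.Series(fractions, name="correct_fraction"),
        q1_vs_q4=q1q4,
        low_expected_warning=bool((expected < 1).any()),
    )
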