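"""Outcome definitions: PSA progression, 2-year responder labels, 7:3 split.

Biochemical progression on androgen deprivation therapy is called when a
PSA measurement simultaneously (i) reaches 2.0 ng/mL or more, (ii) is at
least 50% above the running nadir, and (iii) closes a run of three
consecutive strictly increasing measurements spaced at least one week
apart. A patient who progresses within the 2-year landmark is a
non-responder; a patient followed past the landmark without progression is
a responder; a patient censored before the landmark without progression is
excluded from the landmark analysis (and counted in the exclusion report).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, PwlscoreError

__all__ = [
    "ProgressionCall",
    "SplitAssignment",
    "LandmarkLabels",
    "call_psa_progression",
    "label_responders",
    "split_cohort",
    "LANDMARK_DAYS",
]

#: Default landmark: 2 years expressed in days.
LANDMARK_DAYS = 730

PSA_THRESHOLD = 2.0  # ng/mL
RISE_FACTOR = 1.5  # ≥50% above the nadir
MIN_GAP_DAYS = 7
N_RISES = 3  # consecutive increase steps required


@dataclass(frozen=True)
class ProgressionCall:
    progressed: bool
    progression_day: float | None = None
    trigger: str | None = None  # "psa" or "radiographic"

    def __post_init__(self):
        if self.progressed != (self.progression_day is not None):
            raise InvalidParameterError(
                "progression_day must be present exactly when progressed"
            )


def call_psa_progression(days, values) -> ProgressionCall:
    """Apply the three-clause PSA-progression rule to one measurement series.

    ``days``/``values`` are parallel sequences sorted by day. The running
    nadir for clause (ii) is the minimum over all *earlier* measurements
    (the candidate itself excluded). Clause (iii) needs the candidate to be
    the endpoint of three strict rises, i.e. four ascending measurements,
    each consecutive pair ≥7 days apart. Returns the earliest qualifying
    day.
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if days.shape != values.shape or days.ndim != 1 or days.size == 0:
        raise InvalidParameterError("need parallel non-empty 1-d day/value series")
    if np.any(np.diff(days) < 0):
        raise InvalidParameterError("measurements must be sorted by day")
    if np.any(values < 0) or not np.all(np.isfinite(values)):
        raise InvalidParameterError("PSA values must be finite and non-negative")

    for i in range(N_RISES, len(values)):
        v = values[i]
        if v < PSA_THRESHOLD:
            continue
        nadir = values[:i].min()
        if v < RISE_FACTOR * nadir:
            continue
        window_v = values[i - N_RISES : i + 1]
        window_d = days[i - N_RISES : i + 1]
        if np.all(np.diff(window_v) > 0) and np.all(np.diff(window_d) >= MIN_GAP_DAYS):
            return ProgressionCall(True, float(days[i]), "psa")
    return ProgressionCall(False)


@dataclass
class LandmarkLabels:
    """Responder labels at a landmark plus the exclusion accounting."""

    label: pd.Series  # "responder" | "non-responder" | "excluded"
    landmark_days: float
    n_responders: int = field(init=False)
    n_non_responders: int = field(init=False)
    n_excluded: int = field(init=False)

    def __post_init__(self):
        counts = self.label.value_counts()
        self.n_responders = int(counts.get("responder", 0))
        self.n_non_responders = int(counts.get("non-responder", 0))
        self.n_excluded = int(counts.get("excluded", 0))

    @property
    def binary(self) -> pd.Series:
        """Responder = 1, non-responder = 0; excluded samples dropped."""
        kept = self.label[self.label != "excluded"]
        return (kept == "responder").astype(int)

    @property
    def excluded_ids(self) -> list:
        return list(self.label.index[self.label == "excluded"])


def label_responders(
    progression_day,
    followup_days,
    landmark_days: float = LANDMARK_DAYS,
) -> LandmarkLabels:
    """Landmark responder labelling with pre-landmark-censoring exclusions.

    ``progression_day`` is a per-sample day of progression (NaN/None when no
    progression was observed); ``followup_days`` the per-sample last day of
    follow-up. Non-responder iff progression on or before the landmark;
    responder iff followed to the landmark without such progression;
    otherwise excluded.
    """
    prog = pd.Series(progression_day, dtype=float)
    fup = pd.Series(followup_days, dtype=float)
    if not prog.index.equals(fup.index):
        prog = prog.reset_index(drop=True)
        fup = fup.reset_index(drop=True)
    if (fup < 0).any():
        raise InvalidParameterError("follow-up days must be non-negative")

    progressed_by_landmark = prog.notna() & (prog <= landmark_days)
    followed_to_landmark = fup >= landmark_days
    label = pd.Series("excluded", index=prog.index, dtype=object)
    label[progressed_by_landmark] = "non-responder"
    label[~progressed_by_landmark & followed_to_landmark] = "responder"
    return LandmarkLabels(label=label, landmark_days=landmark_days)


@dataclass(frozen=True)
class SplitAssignment:
    """Random discovery/validation assignment at a fixed ratio."""

    assignment: pd.Series  # sample_id -> "discovery" | "validation"
    seed: int

    @property
    def discovery_ids(self) -> list:
        return list(self.assignment.index[self.assignment == "discovery"])

    @property
    def validation_ids(self) -> list:
        return list(self.assignment.index[self.assignment == "validation"])

    @property
    def sizes(self) -> tuple[int, int]:
        return len(self.discovery_ids), len(self.validation_ids)


def split_cohort(sample_ids, ratio=(7, 3), seed: int = 0) -> SplitAssignment:
    """Simple random split without stratification; validation size floored.

    With ratio (a, b) the validation arm gets ``floor(n·b/(a+b))`` samples
    and discovery the rest, so for n = 10 at 7:3 the sizes are (7, 3).
    """
    ids = list(sample_ids)
    n = len(ids)
    if n < 10:
        raise InvalidParameterError("need at least 10 samples to split")
    a, b = ratio
    n_val = math.floor(n * b / (a + b))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    val_set = {ids[i] for i in order[:n_val]}
    assignment = pd.Series(
        ["validation" if s in val_set else "discovery" for s in ids],
        index=pd.Index(ids, name="sample_id"),
    )
    return SplitAssignment(assignment=assignment, seed=seed)
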