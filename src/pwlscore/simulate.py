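"""Synthetic ADT cohorts: clinical features, HWE genotypes, outcomes.

The generator emulates the statistical structure of a primary-ADT prostate
cancer cohort: mixed binary/quantitative clinical covariates with missing
entries, a SNP panel with genotypes drawn under Hardy–Weinberg equilibrium
at stated minor-allele frequencies, a binary 2-year responder label driven
by a logistic model on the preprocessed feature scale (optionally with
subgroup-heterogeneous effects — the regime where sample-wise weights beat
one global model), and PFS/CSS/OS times from an exponential
proportional-hazards model tied to the same linear predictor. Responders
(high linear predictor) have lower hazard, i.e. longer survival.

Everything is driven by one seed and is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DimensionError, InvalidParameterError

__all__ = [
    "HeterogeneitySpec",
    "SimulationConfig",
    "Cohort",
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_psa_series",
    "default_snp_mafs",
    "DEFAULT_BINARY_FEATURES",
    "DEFAULT_QUANT_FEATURES",
]

# Shipped default clinical profile. Names follow the covariates reported for
# this disease setting (comorbidities, labs, stage/grade); means and SDs are
# plausible values for an elderly advanced-prostate-cancer population, not
# fitted to any dataset. Format: (name, mean, sd).
DEFAULT_BINARY_FEATURES = (
    "hypertension",
    "diabetes_mellitus",
    "dyslipidemia",
    "cerebral_infarction",
)
DEFAULT_QUANT_FEATURES = (
    ("age", 72.0, 8.0),
    ("psa", 3.0, 1.5),  # log scale; raw value is exp(·), ng/mL
    ("gleason_score", 8.5, 1.0),
    ("total_testosterone", 4.5, 1.5),
    ("total_cholesterol", 190.0, 35.0),
    ("lymphocyte_pct", 25.0, 8.0),
    ("alb", 4.0, 0.4),
    ("bun", 16.0, 5.0),
    ("ast", 25.0, 9.0),
    ("n_category", 0.6, 0.5),
    ("m_category", 0.8, 0.4),
    ("eod_grade", 1.8, 1.2),
    ("t_bil", 0.7, 0.25),
    ("glucose", 105.0, 20.0),
    ("ck", 110.0, 45.0),
    ("total_p1np", 70.0, 30.0),
    ("hemoglobin", 13.0, 1.5),
    ("wbc", 6.5, 1.8),
    ("neutrophil", 4.0, 1.4),
)

#: Endpoint → baseline median event time (days) for the exponential model.
BASELINE_MEDIAN_DAYS = {"pfs": 700.0, "css": 2400.0, "os": 2000.0}


def default_snp_mafs(n_snps: int, seed: int = 12345) -> list[float]:
    """A reproducible panel of minor-allele frequencies in [0.05, 0.5]."""
    rng = np.random.default_rng(seed)
    return list(np.round(rng.uniform(0.05, 0.5, size=n_snps), 3))


@dataclass(frozen=True)
class HeterogeneitySpec:
    """Subgroup-specific effect vectors keyed by a binary clinical feature.

    ``feature`` names (or indexes, counting binary features first) the
    binary clinical covariate whose ±1 coding defines the latent subgroup;
    ``effects`` maps coded value (−1 / +1) to a full effect vector on the
    preprocessed scale. The subgroup feature stays in the feature matrix,
    so a sufficiently flexible model can recover the interaction.
    """

    feature: str | int
    effects: dict[int, np.ndarray]

    def __post_init__(self):
        if set(self.effects) != {-1, 1}:
            raise InvalidParameterError("effects must be keyed by -1 and +1")


@dataclass
class SimulationConfig:
    n_samples: int = 119
    n_binary_clinical: int = 4
    n_quant_clinical: int = 19
    snp_mafs: list[float] = field(default_factory=lambda: default_snp_mafs(46))
    effect_vector: np.ndarray | None = None  # length = total feature count
    heterogeneity: HeterogeneitySpec | None = None
    intercept: float = 0.0
    missing_rate: float = 0.05
    censor_rate: float = 0.25
    hazard_scale: float = 0.5
    binary_prevalence: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 10:
            raise InvalidParameterError("n_samples must be >= 10")
        for p in self.snp_mafs:
            if not 0.0 < p <= 0.5:
                raise InvalidParameterError(f"MAF {p} outside (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise InvalidParameterError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.censor_rate < 1.0:
            raise InvalidParameterError("censor_rate must be in [0, 1)")
        if self.hazard_scale < 0:
            raise InvalidParameterError("hazard_scale must be non-negative")
        if self.effect_vector is not None:
            self.effect_vector = np.asarray(self.effect_vector, dtype=float)
            if self.effect_vector.shape != (self.n_features,):
                raise DimensionError(
                    f"effect_vector length {self.effect_vector.size} != "
                    f"feature count {self.n_features}"
                )

    @property
    def n_features(self) -> int:
        return self.n_binary_clinical + self.n_quant_clinical + len(self.snp_mafs)

    def feature_names(self) -> list[str]:
        nb, nq = self.n_binary_clinical, self.n_quant_clinical
        binary = [
            DEFAULT_BINARY_FEATURES[i]
            if i < len(DEFAULT_BINARY_FEATURES)
            else f"comorbidity_{i}"
            for i in range(nb)
        ]
        quant = [
            DEFAULT_QUANT_FEATURES[i][0]
            if i < len(DEFAULT_QUANT_FEATURES)
            else f"lab_{i}"
            for i in range(nq)
        ]
        snps = [f"rs_sim{i:04d}" for i in range(len(self.snp_mafs))]
        return binary + quant + snps

    def to_json(self) -> dict:
        out = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.__dict__.items()
            if k != "heterogeneity"
        }
        if self.heterogeneity is not None:
            out["heterogeneity"] = {
                "feature": self.heterogeneity.feature,
                "effects": {
                    str(k): np.asarray(v).tolist()
                    for k, v in self.heterogeneity.effects.items()
                },
            }
        return out


@dataclass
class Cohort:
    """A simulated (or ingested) cohort on the wide per-sample layout."""

    clinical: pd.DataFrame  # mixed binary(0/1)/quantitative, NaN = missing
    genotypes: pd.DataFrame  # minor-allele counts 0/1/2
    responder: pd.Series  # 1 = responder (no castration resistance at 2y)
    pfs: pd.DataFrame  # columns: time (days), event (0/1)
    css: pd.DataFrame
    os: pd.DataFrame
    linear_predictor: pd.Series | None = None  # simulation ground truth
    config: SimulationConfig | None = None

    def __post_init__(self):
        geno = self.genotypes.to_numpy()
        if geno.size and not np.isin(geno, [0, 1, 2]).all():
            raise InvalidParameterError("genotype values must be in {0, 1, 2}")
        for name in ("pfs", "css", "os"):
            ep = getattr(self, name)
            if (ep["time"] < 0).any():
                raise InvalidParameterError(f"{name}: negative times")
            if not ep["event"].isin([0, 1]).all():
                raise InvalidParameterError(f"{name}: event flags must be 0/1")
        if self.responder.isna().any():
            raise InvalidParameterError("responder label must be defined per sample")

    @property
    def sample_ids(self) -> list:
        return list(self.clinical.index)

    @property
    def n_samples(self) -> int:
        return len(self.clinical)

    def features(self) -> pd.DataFrame:
        """Clinical and genotype columns joined, samples as rows."""
        return self.clinical.join(self.genotypes)

    def write(self, directory: str | Path) -> None:
        """One wide TSV plus a JSON sidecar recording roles, config and seed."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        wide = self.features().copy()
        wide["responder"] = self.responder
        for name in ("pfs", "css", "os"):
            ep = getattr(self, name)
            wide[f"{name}_time"] = ep["time"]
            wide[f"{name}_event"] = ep["event"]
        wide.to_csv(directory / "cohort.tsv", sep="\t", index_label="sample_id")
        sidecar = {
            "clinical_columns": list(self.clinical.columns),
            "genotype_columns": list(self.genotypes.columns),
            "config": self.config.to_json() if self.config else None,
        }
        (directory / "cohort.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def read(cls, directory: str | Path) -> "Cohort":
        directory = Path(directory)
        sidecar = json.loads((directory / "cohort.json").read_text())
        wide = pd.read_csv(directory / "cohort.tsv", sep="\t", index_col="sample_id")
        endpoints = {
            name: wide[[f"{name}_time", f"{name}_event"]].rename(
                columns={f"{name}_time": "time", f"{name}_event": "event"}
            )
            for name in ("pfs", "css", "os")
        }
        return cls(
            clinical=wide[sidecar["clinical_columns"]],
            genotypes=wide[sidecar["genotype_columns"]].astype(int),
            responder=wide["responder"],
            **endpoints,
        )


def simulate_genotypes(mafs, n: int, seed: int = 0) -> np.ndarray:
    """Minor-allele counts (n × n_snps) under HWE at the given frequencies.

    Each genotype is Binomial(2, p), equivalently the HWE class
    probabilities ((1−p)², 2p(1−p), p²) for counts (0, 1, 2).
    """
    mafs = np.asarray(mafs, dtype=float)
    if mafs.ndim != 1 or mafs.size == 0:
        raise InvalidParameterError("need a non-empty 1-d MAF vector")
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise InvalidParameterError("every MAF must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    return rng.binomial(2, mafs, size=(n, mafs.size)).astype(np.int64)


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Draw one full cohort from the configured generative model."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    nb, nq = config.n_binary_clinical, config.n_quant_clinical
    names = config.feature_names()
    bin_names, quant_names = names[:nb], names[nb : nb + nq]
    snp_names = names[nb + nq :]

    # coded scale: binary ±1, quantitative N(0,1), genotypes standardized
    # by their HWE moments (mean 2p, sd sqrt(2p(1-p)))
    bin_raw = (rng.random((n, nb)) < config.binary_prevalence).astype(int)
    bin_coded = 2.0 * bin_raw - 1.0
    quant_coded = rng.standard_normal((n, nq))
    if config.snp_mafs:
        geno = simulate_genotypes(config.snp_mafs, n, seed=rng.integers(2**31))
        mafs = np.asarray(config.snp_mafs, dtype=float)
        geno_coded = (geno - 2.0 * mafs) / np.sqrt(2.0 * mafs * (1.0 - mafs))
    else:
        geno = np.empty((n, 0), dtype=np.int64)
        geno_coded = np.empty((n, 0))
    coded = np.hstack([bin_coded, quant_coded, geno_coded])

    if config.effect_vector is not None:
        beta = config.effect_vector
    else:
        beta = np.zeros(config.n_features)
    eta = config.intercept + coded @ beta
    if config.heterogeneity is not None:
        spec = config.heterogeneity
        idx = (
            bin_names.index(spec.feature)
            if isinstance(spec.feature, str)
            else int(spec.feature)
        )
        subgroup = bin_coded[:, idx].astype(int)
        eta = np.empty(n)
        for g in (-1, 1):
            vec = np.asarray(spec.effects[g], dtype=float)
            if vec.shape != (config.n_features,):
                raise DimensionError("heterogeneity effect vector length mismatch")
            mask = subgroup == g
            eta[mask] = config.intercept + coded[mask] @ vec

    responder = rng.binomial(1, _sigmoid(eta))

    # raw clinical table; quantitative raw = mean + sd * z (psa on log scale)
    clinical = pd.DataFrame(index=pd.Index(range(n), name="sample_id"))
    for j, name in enumerate(bin_names):
        clinical[name] = bin_raw[:, j]
    for j, name in enumerate(quant_names):
        profile = dict((q[0], (q[1], q[2])) for q in DEFAULT_QUANT_FEATURES)
        mu, sd = profile.get(name, (0.0, 1.0))
        raw = mu + sd * quant_coded[:, j]
        clinical[name] = np.exp(raw) if name == "psa" else raw
    clinical = clinical.astype(float)

    if config.missing_rate > 0:
        mask = rng.random(clinical.shape) < config.missing_rate
        clinical = clinical.mask(mask)

    genotypes = pd.DataFrame(geno, index=clinical.index, columns=snp_names)

    endpoints = {}
    for name, median_days in BASELINE_MEDIAN_DAYS.items():
        lam = (np.log(2.0) / median_days) * np.exp(-config.hazard_scale * eta)
        t_event = rng.exponential(1.0 / lam)
        censored = rng.random(n) < config.censor_rate
        time = np.where(censored, rng.random(n) * t_event, t_event)
        endpoints[name] = pd.DataFrame(
            {"time": np.ceil(time), "event": (~censored).astype(int)},
            index=clinical.index,
        )

    return Cohort(
        clinical=clinical,
        genotypes=genotypes,
        responder=pd.Series(responder, index=clinical.index, name="responder"),
        pfs=endpoints["pfs"],
        css=endpoints["css"],
        os=endpoints["os"],
        linear_predictor=pd.Series(eta, index=clinical.index, name="eta"),
        config=config,
    )


def simulate_psa_series(
    n: int, progression_fraction: float, seed: int = 0
) -> pd.DataFrame:
    """Long-format PSA series (sample_id, day, psa) with an exact progressor count.

    Exactly ``round(progression_fraction · n)`` series are constructed to
    satisfy the full progression rule (≥2.0 ng/mL, ≥50% above nadir, three
    ≥7-day-spaced consecutive rises); the rest each violate one clause
    (below threshold / insufficient rise / rises too closely spaced), cycling
    through the three failure modes.
    """
    if not 0.0 <= progression_fraction <= 1.0:
        raise InvalidParameterError("progression_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_prog = round(progression_fraction * n)
    rows = []
    for sid in range(n):
        jitter = rng.uniform(0.9, 1.1)
        if sid < n_prog:
            # decline to a nadir, then three ≥7-day rises through 2.0 and 1.5×nadir
            nadir = 0.8 * jitter
            days = [0, 30, 60, 74, 88, 102]
            values = [5.0 * jitter, nadir, nadir * 1.4, nadir * 1.9, nadir * 2.6, nadir * 3.5]
        else:
            mode = sid % 3
            if mode == 0:  # never reaches 2.0 ng/mL
                nadir = 0.5 * jitter
                days = [0, 30, 60, 74, 88]
                values = [1.8 * jitter, nadir, nadir * 1.6, nadir * 2.0, min(nadir * 2.4, 1.9)]
            elif mode == 1:  # above 2.0 but never ≥50% over the nadir
                nadir = 1.8 * jitter
                days = [0, 30, 60, 74, 88]
                values = [2.6 * jitter, nadir, nadir * 1.1, nadir * 1.2, nadir * 1.3]
            else:  # rises spaced < 7 days, run broken
                nadir = 0.8 * jitter
                days = [0, 30, 60, 74, 78]
                values = [5.0 * jitter, nadir, nadir * 1.4, nadir * 1.9, nadir * 3.0]
        for d, v in zip(days, values):
            rows.append({"sample_id": sid, "day": d, "psa": float(v)})
    return pd.DataFrame(rows)
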