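"""End-to-end orchestration of the analysis on one cohort.

The flow mirrors the study design: split 7:3 into discovery/validation,
freeze the feature coding on discovery, train the point-wise linear model
and the two baselines per feature set under a shared 5-fold CV, extract
important features from the discovery sample-wise weights, build simple
prediction scores, stratify pooled scores into quartiles, and evaluate the
quartile groups against the responder label (chi-square) and the three
survival endpoints (Kaplan–Meier, log-rank, Harrell's C). Every stage is a
pure function of (cohort, config, seed); intermediates are written as
delimited text plus JSON sidecars.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .baselines import DEFAULT_GRIDS, evaluate_model, make_baseline
from .errors import PwlscoreError, SchemaError
from .importance import (
    build_importance_report,
    extract_features,
    quartile_groups,
    simple_score,
)
from .labels import split_cohort
from .preprocessing import ClinicalPreprocessor, encode_genotypes
from .pwl import DEFAULT_PWL_GRID, PointwiseLinearClassifier, select_hyperparams_cv
from .simulate import Cohort, SimulationConfig, simulate_cohort
from .survival import harrell_c, km_estimate, logrank_test, quartile_response_table

__all__ = ["RunConfig", "RunReport", "run_full", "compare_models"]

logger = logging.getLogger(__name__)

MODEL_KINDS = ("pwl", "elastic_net_lr", "gradient_boosting")


@dataclass
class RunConfig:
    """Configuration for one full analysis run."""

    simulation: SimulationConfig | None = None
    cohort_dir: str | None = None  # alternative to simulation
    feature_sets: dict[str, list[str]] | None = None  # name -> genotype columns
    models: tuple[str, ...] = MODEL_KINDS
    seed: int = 0
    cv_folds: int = 5
    threshold_rule: str = "youden"
    importance_cutoff: float = 0.1
    top_fraction: float = 0.1
    pwl_grid: dict = field(default_factory=lambda: dict(DEFAULT_PWL_GRID))
    baseline_grids: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GRIDS.items()})
    pwl_params: dict = field(default_factory=dict)  # overrides (epochs, width, ...)
    out_dir: str | None = None

    def resolve_cohort(self) -> Cohort:
        if (self.simulation is None) == (self.cohort_dir is None):
            raise PwlscoreError("configure exactly one of simulation / cohort_dir")
        if self.cohort_dir is not None:
            return Cohort.read(self.cohort_dir)
        return simulate_cohort(self.simulation)


@dataclass
class RunReport:
    performance: pd.DataFrame  # model × feature set × cohort metrics
    rankings: pd.DataFrame
    importance: dict[str, pd.DataFrame]  # feature set -> extracted feature table
    simple_models: dict[str, pd.DataFrame]
    scores: dict[str, pd.Series]
    quartiles: dict[str, pd.Series]
    quartile_tables: dict[str, dict]
    survival: pd.DataFrame  # feature set × endpoint: logrank stat/p, C-index
    km_curves: dict[str, dict[str, dict[str, pd.DataFrame]]]
    split_sizes: tuple[int, int]

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.performance.to_csv(directory / "performance.tsv", sep="\t", index=False)
        self.rankings.to_csv(directory / "model_ranking.tsv", sep="\t", index=False)
        self.survival.to_csv(directory / "survival_eval.tsv", sep="\t", index=False)
        for fs, table in self.importance.items():
            table.to_csv(directory / f"importance_{fs}.tsv", sep="\t", index=False)
        for fs, table in self.simple_models.items():
            table.to_csv(directory / f"simple_model_{fs}.tsv", sep="\t", index=False)
        for fs, s in self.scores.items():
            pd.DataFrame({"simple_score": s, "quartile": self.quartiles[fs]}).to_csv(
                directory / f"scores_{fs}.tsv", sep="\t", index_label="sample_id"
            )
        for fs, curves in self.km_curves.items():
            for endpoint, per_group in curves.items():
                frames = []
                for g, tab in per_group.items():
                    t = tab.copy()
                    t.insert(0, "group", g)
                    frames.append(t)
                pd.concat(frames).to_csv(
                    directory / f"km_{fs}_{endpoint}.tsv", sep="\t", index=False
                )
        summary = {
            "split_sizes": list(self.split_sizes),
            "quartile_tables": {
                fs: {
                    "chi2": tab["chi2"],
                    "df": tab["df"],
                    "p": tab["p"],
                    "q1_vs_q4": tab["q1_vs_q4"],
                    "correct_fractions": tab["correct_fractions"],
                }
                for fs, tab in self.quartile_tables.items()
            },
        }
        (directory / "summary.json").write_text(json.dumps(summary, indent=2))


def _default_feature_sets(cohort: Cohort) -> dict[str, list[str]]:
    snps = list(cohort.genotypes.columns)
    sets = {"clinical": []}
    if len(snps) >= 2:
        sets["clinical+small_snp"] = snps[:2]
    if snps:
        sets["clinical+large_snp"] = snps
    return sets


def run_full(config: RunConfig) -> RunReport:
    """Execute every stage with a single master seed; returns the report."""
    cohort = config.resolve_cohort()
    feature_sets = config.feature_sets or _default_feature_sets(cohort)
    for name, snp_cols in feature_sets.items():
        missing = [c for c in snp_cols if c not in cohort.genotypes.columns]
        if missing:
            raise SchemaError(f"feature set {name!r} references unknown SNPs {missing}")

    split = split_cohort(cohort.sample_ids, seed=config.seed)
    disc_ids, val_ids = split.discovery_ids, split.validation_ids
    y = cohort.responder
    y_disc, y_val = y.loc[disc_ids], y.loc[val_ids]
    logger.info("split: %d discovery / %d validation", len(disc_ids), len(val_ids))

    perf_rows, rank_rows = [], []
    importance, simple_models, scores, quartiles = {}, {}, {}, {}
    quartile_tables, surv_rows, km_curves = {}, [], {}

    for fs_name, snp_cols in feature_sets.items():
        raw = cohort.clinical.join(encode_genotypes(cohort.genotypes[snp_cols]))
        pre = ClinicalPreprocessor().fit(raw.loc[disc_ids])
        X_all = pre.transform(raw)
        X_disc, X_val = X_all.loc[disc_ids], X_all.loc[val_ids]

        fitted = {}
        for model_kind in config.models:
            if model_kind == "pwl":
                est = PointwiseLinearClassifier(
                    random_state=config.seed, **config.pwl_params
                )
                grid = config.pwl_grid
            else:
                est = make_baseline(model_kind, seed=config.seed)
                grid = config.baseline_grids[model_kind]
            cv = select_hyperparams_cv(
                est, X_disc, y_disc, grid, k=config.cv_folds, seed=config.seed
            )
            fitted[model_kind] = cv
            ev_val = evaluate_model(
                cv.best_estimator, X_val, y_val, config.threshold_rule
            )
            ev_disc = evaluate_model(
                cv.best_estimator, X_disc, y_disc, config.threshold_rule
            )
            perf_rows.append(
                {
                    "feature_set": fs_name,
                    "model": model_kind,
                    "discovery_cv_auc": cv.best_mean_auc,
                    "discovery_sensitivity": ev_disc.sensitivity,
                    "discovery_specificity": ev_disc.specificity,
                    "validation_auc": ev_val.auc,
                    "validation_sensitivity": ev_val.sensitivity,
                    "validation_specificity": ev_val.specificity,
                }
            )

        if "pwl" in fitted:
            pwl_model = fitted["pwl"].best_estimator
            weights_disc = pwl_model.sample_weights(X_disc)
            report = build_importance_report(
                weights_disc,
                feature_names=list(X_disc.columns),
                top_fraction=config.top_fraction,
                cutoff=config.importance_cutoff,
            )
            importance[fs_name] = report.ranked_table()
            try:
                model = extract_features(report)
            except PwlscoreError as exc:
                logger.warning("feature set %s: %s", fs_name, exc)
                continue
            simple_models[fs_name] = model.to_frame()
            s = simple_score(model, X_all)
            scores[fs_name] = s
            grouping = quartile_groups(s)
            quartiles[fs_name] = grouping.groups
            ct = quartile_response_table(grouping.groups, y)
            quartile_tables[fs_name] = {
                "chi2": ct.statistic,
                "df": ct.df,
                "p": ct.p_value,
                "q1_vs_q4": ct.q1_vs_q4,
                "correct_fractions": ct.correct_fractions.to_dict(),
            }
            km_curves[fs_name] = {}
            for endpoint in ("pfs", "css", "os"):
                ep = getattr(cohort, endpoint)
                km_curves[fs_name][endpoint] = km_estimate(
                    ep["time"], ep["event"], grouping.groups
                )
                lr = logrank_test(ep["time"], ep["event"], grouping.groups)
                c = harrell_c(ep["time"], ep["event"], s.to_numpy())
                surv_rows.append(
                    {
                        "feature_set": fs_name,
                        "endpoint": endpoint.upper(),
                        "logrank_stat": lr.statistic,
                        "logrank_df": lr.df,
                        "logrank_p": lr.p_value,
                        "c_index": c,
                    }
                )

    performance = pd.DataFrame(perf_rows)
    rankings = compare_models(performance)
    report = RunReport(
        performance=performance,
        rankings=rankings,
        importance=importance,
        simple_models=simple_models,
        scores=scores,
        quartiles=quartiles,
        quartile_tables=quartile_tables,
        survival=pd.DataFrame(surv_rows),
        km_curves=km_curves,
        split_sizes=split.sizes,
    )
    if config.out_dir:
        report.write(config.out_dir)
    return report


def compare_models(performance: pd.DataFrame) -> pd.DataFrame:
    """Rank models per feature set by validation AUC.

    Ties break by discovery mean CV AUC, then by model name for
    determinism.
    """
    rows = []
    for fs, sub in performance.groupby("feature_set", sort=True):
        ordered = sub.sort_values(
            ["validation_auc", "discovery_cv_auc", "model"],
            ascending=[False, False, True],
        )
        for rank, (_, row) in enumerate(ordered.iterrows(), start=1):
            rows.append(
                {
                    "feature_set": fs,
                    "rank": rank,
                    "model": row["model"],
                    "validation_auc": row["validation_auc"],
                    "discovery_cv_auc": row["discovery_cv_auc"],
                }
            )
    return pd.DataFrame(rows)
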