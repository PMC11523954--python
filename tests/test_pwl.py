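"""The point-wise linear classifier and its CV selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from pwlscore import (
    DegenerateLabelError,
    HeterogeneitySpec,
    PointwiseLinearClassifier,
    SimulationConfig,
    build_importance_report,
    fit_baseline,
    select_hyperparams_cv,
    simulate_cohort,
    split_cohort,
)
from pwlscore.errors import DimensionError
from pwlscore.preprocessing import ClinicalPreprocessor

FAST = dict(hidden_width=16, depth=2, epochs=150)


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((500, 5))
    beta = np.array([3.0, -3.0, 2.0, 0.0, 0.0])
    y = (X @ beta > 0).astype(int)
    return X, y


class TestGradients:
    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((6, 3))
        y = rng.integers(0, 2, 6).astype(float)
        clf = PointwiseLinearClassifier(
            hidden_width=4, depth=2, weight_decay=0.01, weight_penalty=0.1
        )
        params = clf._init_params(3, np.random.default_rng(1))
        _, grads = clf._grads(params, X, y)
        eps = 1e-6
        for arr, g in zip(clf._flatten(params), clf._flatten(grads)):
            flat_idx = np.unravel_index(
                np.argmax(np.abs(g)), g.shape
            )  # check the steepest entry of each parameter array
            old = arr[flat_idx]
            arr[flat_idx] = old + eps
            lp, _ = clf._grads(params, X, y)
            arr[flat_idx] = old - eps
            lm, _ = clf._grads(params, X, y)
            arr[flat_idx] = old
            assert (lp - lm) / (2 * eps) == pytest.approx(g[flat_idx], rel=1e-4)


class TestFitPredict:
    def test_separable_data_fit_to_high_auc(self, separable):
        X, y = separable
        clf = PointwiseLinearClassifier(random_state=0).fit(X, y)
        assert roc_auc_score(y, clf.decision_function(X)) >= 0.99

    def test_training_loss_decreases(self, separable):
        X, y = separable
        clf = PointwiseLinearClassifier(random_state=0, **FAST).fit(X, y)
        assert clf.loss_curve_[-1] <= clf.loss_curve_[0]

    def test_null_labels_stay_at_chance_in_cv(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((500, 5))
        y = rng.integers(0, 2, 500)
        cv = select_hyperparams_cv(
            PointwiseLinearClassifier(random_state=0, **FAST),
            X,
            y,
            {"weight_decay": [1e-3]},
            seed=0,
        )
        assert 0.35 <= cv.best_mean_auc <= 0.65

    def test_predictions_consistent_with_emitted_weights(self, separable):
        X, y = separable
        clf = PointwiseLinearClassifier(random_state=0, **FAST).fit(X, y)
        sw = clf.sample_weights(X)
        z = np.einsum("ij,ij->i", sw.weights, X) + sw.intercepts
        p = 1 / (1 + np.exp(-z))
        assert np.abs(clf.predict_proba(X)[:, 1] - p).max() < 1e-6

    def test_null_generator_outputs_half(self, separable):
        X, y = separable
        clf = PointwiseLinearClassifier(random_state=0, epochs=1).fit(X, y)
        clf.params_["Wo"][:] = 0.0  # force (w, b) = (0, 0) for every sample
        clf.params_["bo"][:] = 0.0
        assert np.allclose(clf.predict_proba(X)[:, 1], 0.5)

    def test_duplicate_rows_get_identical_probabilities(self, separable):
        X, y = separable
        clf = PointwiseLinearClassifier(random_state=0, **FAST).fit(X, y)
        X2 = np.vstack([X[:3], X[:3]])
        p = clf.predict_proba(X2)[:, 1]
        assert np.array_equal(p[:3], p[3:])

    def test_permuting_samples_permutes_weights(self, separable):
        X, y = separable
        clf = PointwiseLinearClassifier(random_state=0, **FAST).fit(X, y)
        perm = np.random.default_rng(2).permutation(len(X))
        sw = clf.sample_weights(X)
        sw_perm = clf.sample_weights(X[perm])
        assert np.array_equal(sw.weights[perm], sw_perm.weights)

    def test_zero_feature_row_predicts_sigmoid_of_intercept(self, separable):
        X, y = separable
        clf = PointwiseLinearClassifier(random_state=0, **FAST).fit(X, y)
        row = np.zeros((1, 5))
        sw = clf.sample_weights(row)
        expected = 1 / (1 + np.exp(-sw.intercepts[0]))
        assert clf.predict_proba(row)[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_same_seed_identical_fit(self, separable):
        X, y = separable
        a = PointwiseLinearClassifier(random_state=5, **FAST).fit(X, y)
        b = PointwiseLinearClassifier(random_state=5, **FAST).fit(X, y)
        for pa, pb in zip(a._flatten(a.params_), b._flatten(b.params_)):
            assert np.array_equal(pa, pb)
        assert np.array_equal(a.decision_function(X), b.decision_function(X))

    def test_single_class_labels_rejected(self):
        X = np.random.default_rng(0).standard_normal((20, 3))
        with pytest.raises(DegenerateLabelError):
            PointwiseLinearClassifier().fit(X, np.zeros(20))

    def test_feature_count_mismatch_rejected(self, separable):
        X, y = separable
        clf = PointwiseLinearClassifier(random_state=0, **FAST).fit(X, y)
        with pytest.raises(DimensionError):
            clf.predict_proba(X[:, :3])


class TestRecoveryRegimes:
    def test_median_weights_track_global_coefficients(self):
        """Homogeneous logistic data: per-sample weights concentrate on β."""
        beta = np.zeros(10)
        beta[:4] = [2.0, -2.0, 1.5, -1.5]
        cfg = SimulationConfig(
            n_samples=2000,
            n_binary_clinical=0,
            n_quant_clinical=10,
            snp_mafs=[],
            effect_vector=beta,
            missing_rate=0.0,
            seed=21,
        )
        cohort = simulate_cohort(cfg)
        pre = ClinicalPreprocessor().fit(cohort.clinical)
        X = pre.transform(cohort.clinical)
        clf = PointwiseLinearClassifier(random_state=21).fit(X, cohort.responder)
        median_w = np.median(clf.sample_weights(X).weights, axis=0)
        rho = stats.spearmanr(median_w, beta).statistic
        assert rho >= 0.8

    def test_subgroup_flip_advantage_over_global_model(self):
        """Opposite-sign subgroups: sample-wise weights beat elastic-net LR."""
        d = 10
        base = np.zeros(d)
        base[1:4] = 2.0
        spec = HeterogeneitySpec(feature=0, effects={1: base, -1: -base})
        cfg = SimulationConfig(
            n_samples=2000,
            n_binary_clinical=1,
            n_quant_clinical=9,
            snp_mafs=[],
            heterogeneity=spec,
            missing_rate=0.0,
            seed=22,
        )
        cohort = simulate_cohort(cfg)
        split = split_cohort(cohort.sample_ids, seed=22)
        pre = ClinicalPreprocessor().fit(cohort.clinical.loc[split.discovery_ids])
        Xd = pre.transform(cohort.clinical.loc[split.discovery_ids])
        Xv = pre.transform(cohort.clinical.loc[split.validation_ids])
        yd = cohort.responder.loc[split.discovery_ids]
        yv = cohort.responder.loc[split.validation_ids]
        pwl = PointwiseLinearClassifier(random_state=22).fit(Xd, yd)
        lr = fit_baseline("elastic_net_lr", Xd, yd, seed=22)
        auc_pwl = roc_auc_score(yv, pwl.decision_function(Xv))
        auc_lr = roc_auc_score(yv, lr.predict_proba(Xv)[:, 1])
        assert auc_pwl - auc_lr >= 0.05

    def test_homogeneous_data_matches_global_model(self):
        """No heterogeneity: PWL and elastic-net LR agree to within 0.05 AUC."""
        beta = np.zeros(8)
        beta[:3] = [1.5, -1.0, 1.0]
        cfg = SimulationConfig(
            n_samples=2000,
            n_binary_clinical=0,
            n_quant_clinical=8,
            snp_mafs=[],
            effect_vector=beta,
            missing_rate=0.0,
            seed=23,
        )
        cohort = simulate_cohort(cfg)
        split = split_cohort(cohort.sample_ids, seed=23)
        pre = ClinicalPreprocessor().fit(cohort.clinical.loc[split.discovery_ids])
        Xd = pre.transform(cohort.clinical.loc[split.discovery_ids])
        Xv = pre.transform(cohort.clinical.loc[split.validation_ids])
        yd = cohort.responder.loc[split.discovery_ids]
        yv = cohort.responder.loc[split.validation_ids]
        pwl = PointwiseLinearClassifier(random_state=23).fit(Xd, yd)
        lr = fit_baseline("elastic_net_lr", Xd, yd, seed=23)
        auc_pwl = roc_auc_score(yv, pwl.decision_function(Xv))
        auc_lr = roc_auc_score(yv, lr.predict_proba(Xv)[:, 1])
        assert abs(auc_pwl - auc_lr) <= 0.05


class TestCvSelection:
    def test_single_grid_point_selected(self, separable):
        X, y = separable
        cv = select_hyperparams_cv(
            PointwiseLinearClassifier(random_state=0, **FAST),
            X,
            y,
            {"weight_decay": [1e-3]},
            seed=0,
        )
        assert cv.best_params == {"weight_decay": 1e-3}
        assert len(cv.fold_aucs[0]) == 5
        assert cv.best_mean_auc == pytest.approx(np.mean(cv.fold_aucs[0]))

    def test_degenerate_learning_rate_not_selected(self, separable):
        X, y = separable
        cv = select_hyperparams_cv(
            PointwiseLinearClassifier(random_state=0, **FAST),
            X,
            y,
            {"learning_rate": [0.0, 1e-3]},
            seed=0,
        )
        assert cv.best_params["learning_rate"] == 1e-3

    def test_discovery_fold_sizes_balanced(self):
        # the stratified partition convention used for selection, at n = 82
        y = np.array([0] * 50 + [1] * 32)
        folds = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        sizes = sorted(len(test) for _, test in folds.split(np.zeros((82, 1)), y))
        assert sizes == [16, 16, 16, 17, 17]

    def test_too_few_samples_rejected(self):
        with pytest.raises(Exception):
            select_hyperparams_cv(
                PointwiseLinearClassifier(),
                np.zeros((3, 2)),
                np.array([0, 1, 0]),
                {"depth": [2]},
                k=5,
            )
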