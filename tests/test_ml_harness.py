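"""Cross-validation machinery, metrics and the classifier battery."""

import numpy as np
import pandas as pd
import pytest

from _oracles import oracle_aucroc
from swaylift.ml_harness import (
    CLASSIFIER_SPECS,
    METRIC_NAMES,
    ConfusionMatrix,
    CVConfig,
    HarnessError,
    PNNClassifier,
    RotationForestClassifier,
    aucroc,
    backward_feature_elimination,
    build_estimator,
    metrics_from_confusion,
    minmax_scale,
    run_cv_experiment,
    stratified_folds,
)
from swaylift.sway_features import FEATURE_NAMES

NO_RISK, RISK = "No-Risk", "Risk"


def toy_table(n_per_class=30, n_features=2, separation=5.0, seed=0):
    """Linearly separable two-class table using real feature names."""
    rng = np.random.default_rng(seed)
    names = FEATURE_NAMES[:n_features]
    rows = []
    for label, shift in ((NO_RISK, 0.0), (RISK, separation)):
        for _ in range(n_per_class):
            rows.append({"label": label,
                         **{f: rng.normal(shift, 1.0) for f in names}})
    return pd.DataFrame(rows)


class TestFolds:
    def test_balanced_partition(self):
        y = [NO_RISK] * 50 + [RISK] * 50
        folds = stratified_folds(y, CVConfig(k=10, seed=0))
        assert len(folds) == 10
        for _, te in folds:
            labels = np.asarray(y)[te]
            assert len(te) == 10
            assert (labels == NO_RISK).sum() == 5

    def test_test_folds_partition_index_set(self):
        y = [NO_RISK] * 37 + [RISK] * 41
        folds = stratified_folds(y, CVConfig(k=10, seed=1))
        pooled = np.concatenate([te for _, te in folds])
        assert sorted(pooled) == list(range(78))

    def test_deterministic_under_seed(self):
        y = [NO_RISK] * 30 + [RISK] * 30
        f1 = stratified_folds(y, CVConfig(k=5, seed=7))
        f2 = stratified_folds(y, CVConfig(k=5, seed=7))
        for (_, a), (_, b) in zip(f1, f2):
            assert np.array_equal(a, b)

    def test_small_class_rejected(self):
        with pytest.raises(HarnessError):
            stratified_folds([NO_RISK] * 50 + [RISK] * 5, CVConfig(k=10))


class TestMinMax:
    def test_span_maps_to_unit_interval(self):
        train = np.array([[2.0], [4.0], [3.0]])
        scaled, _ = minmax_scale(train, train)
        assert scaled.ravel() == pytest.approx([0.0, 1.0, 0.5])

    def test_constant_feature_maps_to_zero(self):
        train = np.full((4, 1), 7.0)
        scaled, ev = minmax_scale(train, np.array([[9.0]]))
        assert not scaled.any() and not ev.any()

    def test_eval_values_not_clipped(self):
        train = np.array([[2.0], [4.0]])
        _, ev = minmax_scale(train, np.array([[5.0]]))
        assert ev.ravel()[0] == pytest.approx(1.5)


class TestMetrics:
    def test_reported_study_confusion_matrix(self):
        # 306 pooled test instances: actual No-Risk (145, 8), actual Risk (19, 134)
        cm = ConfusionMatrix(145, 8, 19, 134)
        m = metrics_from_confusion(cm)
        assert round(m["accuracy"], 3) == 0.912
        assert round(m["f_measure"], 3) == 0.915
        assert round(m["sensitivity"], 3) == 0.948
        assert round(m["specificity"], 3) == 0.876
        assert round(m["precision"], 3) == 0.884
        assert m["recall"] == m["sensitivity"]
        assert cm.total == 306

    def test_perfect_classifier(self):
        m = metrics_from_confusion(ConfusionMatrix(10, 0, 0, 10))
        assert all(m[k] == 1.0 for k in m)

    def test_degenerate_all_positive_prediction(self):
        m = metrics_from_confusion(ConfusionMatrix(10, 0, 10, 0))
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 0.0

    def test_undefined_metric_is_nan_not_zero(self):
        m = metrics_from_confusion(ConfusionMatrix(0, 0, 0, 10))
        assert np.isnan(m["sensitivity"])
        assert np.isnan(m["precision"])

    def test_swapping_positive_class_swaps_sensitivity_specificity(self):
        m = metrics_from_confusion(ConfusionMatrix(40, 10, 5, 45))
        swapped = metrics_from_confusion(ConfusionMatrix(45, 5, 10, 40))
        assert m["sensitivity"] == swapped["specificity"]
        assert m["specificity"] == swapped["sensitivity"]


class TestAUCROC:
    def test_perfect_separation(self):
        labels = [NO_RISK] * 3 + [RISK] * 3
        assert aucroc([0.9, 0.8, 0.7, 0.3, 0.2, 0.1], labels) == 1.0

    def test_uninformative_scores(self):
        labels = [NO_RISK] * 5 + [RISK] * 5
        assert aucroc([0.5] * 10, labels) == 0.5

    def test_matches_pairwise_oracle_and_reference_library(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        scores = rng.random(20).round(1)  # rounding forces ties
        labels = np.where(rng.random(20) < 0.5, NO_RISK, RISK)
        if len(set(labels)) < 2:
            labels[0] = NO_RISK if labels[0] == RISK else RISK
        ours = aucroc(scores, labels)
        assert ours == pytest.approx(oracle_aucroc(scores, labels, NO_RISK))
        assert ours == pytest.approx(roc_auc_score(labels == NO_RISK, scores))

    def test_single_class_rejected(self):
        with pytest.raises(HarnessError):
            aucroc([0.1, 0.2], [NO_RISK, NO_RISK])


class TestBFE:
    def test_single_feature_is_kept(self):
        table = toy_table(n_features=1)
        sel = backward_feature_elimination(
            table, CLASSIFIER_SPECS["DT"], CVConfig(k=5, seed=0)
        )
        assert sel == [FEATURE_NAMES[0]]

    def test_informative_feature_survives_noise(self):
        rng = np.random.default_rng(0)
        hits = 0
        for seed in range(10):
            n = 60
            labels = np.array([NO_RISK, RISK] * (n // 2))
            table = pd.DataFrame({
                "label": labels,
                "MDIST": np.where(labels == NO_RISK, 0.0, 1.0),
                **{f: rng.standard_normal(n)
                   for f in ["MDIST_AP", "MDIST_ML", "RDIST", "RDIST_AP", "RDIST_ML"]},
            })
            sel = backward_feature_elimination(
                table, CLASSIFIER_SPECS["DT"], CVConfig(k=5, seed=seed)
            )
            hits += "MDIST" in sel
        assert hits > 5

    def test_selection_never_hurts_cv_accuracy(self):
        from swaylift.ml_harness import _cv_accuracy, _validate_table

        table = toy_table(n_features=4, separation=1.0, seed=5)
        spec = CLASSIFIER_SPECS["DT"]
        cv = CVConfig(k=5, seed=2)
        X, y, features = _validate_table(table)
        folds = stratified_folds(y, cv)
        sel = backward_feature_elimination(table, spec, cv, folds)
        idx = [features.index(f) for f in sel]
        assert _cv_accuracy(X[:, idx], y, spec, folds, cv.seed) >= _cv_accuracy(
            X, y, spec, folds, cv.seed
        )


class TestCVExperiment:
    def test_separable_data_classified_perfectly(self):
        report = run_cv_experiment(
            toy_table(), CLASSIFIER_SPECS["GB"], CVConfig(k=10, seed=0)
        )
        assert report.metrics["accuracy"] == 1.0
        assert report.metrics["aucroc"] == 1.0

    def test_pooled_confusion_counts_every_instance_once(self, default_feature_table):
        report = run_cv_experiment(
            default_feature_table, CLASSIFIER_SPECS["DT"], CVConfig(k=10, seed=0)
        )
        assert report.confusion.total == len(default_feature_table)

    def test_report_carries_the_seven_metrics(self):
        report = run_cv_experiment(
            toy_table(), CLASSIFIER_SPECS["kNN"], CVConfig(k=5, seed=0)
        )
        assert sorted(report.metrics) == sorted(METRIC_NAMES)

    def test_deterministic_under_seed(self, default_feature_table):
        runs = [
            run_cv_experiment(
                default_feature_table, CLASSIFIER_SPECS["GB"], CVConfig(k=10, seed=4)
            )
            for _ in range(2)
        ]
        assert runs[0].metrics == runs[1].metrics
        assert runs[0].confusion == runs[1].confusion

    @pytest.mark.parametrize("name", ["SVM", "MLP", "RaF", "XGB", "RoF", "PNN"])
    def test_battery_members_run(self, name):
        report = run_cv_experiment(
            toy_table(n_per_class=15), CLASSIFIER_SPECS[name], CVConfig(k=3, seed=0)
        )
        assert report.metrics["accuracy"] > 0.9  # trivially separable


class TestCustomEstimators:
    def test_pnn_learns_separable_data(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.3, (20, 2)), rng.normal(3, 0.3, (20, 2))])
        y = np.array([NO_RISK] * 20 + [RISK] * 20)
        clf = PNNClassifier().fit(X, y)
        assert (clf.predict(X) == y).all()
        proba = clf.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_rotation_forest_learns_separable_data(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.3, (20, 4)), rng.normal(3, 0.3, (20, 4))])
        y = np.array([NO_RISK] * 20 + [RISK] * 20)
        clf = RotationForestClassifier(random_state=0).fit(X, y)
        assert (clf.predict(X) == y).all()

    def test_unknown_classifier_rejected(self):
        from swaylift.ml_harness import ClassifierSpec

        with pytest.raises(HarnessError):
            build_estimator(ClassifierSpec("nope"))

    def test_scaling_flags(self):
        assert CLASSIFIER_SPECS["kNN"].needs_scaling
        assert CLASSIFIER_SPECS["MLP"].needs_scaling
        assert CLASSIFIER_SPECS["SVM"].needs_scaling
        assert not CLASSIFIER_SPECS["GB"].needs_scaling
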