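"""Metrics arithmetic, cross-validation harness, and the full pipeline."""

import numpy as np
import pytest

from fundusnet.evaluation import (
    ClassifierSpec,
    PipelineConfig,
    f_score,
    macro_average,
    per_class_metrics,
    run_pipeline,
    stratified_cv,
)
from fundusnet.model import ModelConfig, TrainConfig
from fundusnet.synthdata import SynthImageSpec, SynthTableSpec, generate_feature_table, generate_phantom_images


class TestPerClassMetrics:
    def test_perfect_diagonal_scores_one_everywhere(self):
        report = per_class_metrics(np.diag([5, 7, 9]))
        for metric in ("sensitivity", "specificity", "precision", "f_score"):
            np.testing.assert_allclose(report.per_class[metric], 1.0)
        assert report.accuracy == 1.0

    def test_published_amd_row_f_score(self):
        # sens 0.8020 with prec 0.9916 must give F = 0.8868 at 4 decimals
        assert f_score(0.8020, 0.9916) == pytest.approx(0.8868, abs=1e-4)

    def test_two_class_confusion_hand_computed(self):
        report = per_class_metrics(np.array([[8, 2], [1, 9]]))
        sens, spec = report.per_class["sensitivity"], report.per_class["specificity"]
        prec = report.per_class["precision"]
        assert sens[0] == pytest.approx(0.8)
        assert spec[0] == pytest.approx(0.9)
        assert prec[0] == pytest.approx(8 / 9)
        assert report.per_class["f_score"][0] == pytest.approx(
            2 * 0.8 * (8 / 9) / (0.8 + 8 / 9)
        )
        assert report.accuracy == pytest.approx(17 / 20)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            per_class_metrics(np.ones((2, 3)))

    def test_empty_prediction_column_yields_nan_with_warning(self):
        cm = np.array([[3, 0], [2, 0]])  # nothing ever predicted as class 1
        with pytest.warns(UserWarning, match="undefined"):
            report = per_class_metrics(cm)
        assert np.isnan(report.per_class["precision"][1])

    def test_confusion_row_sums_equal_class_counts(self):
        cm = np.array([[4, 1, 0], [2, 6, 1], [0, 0, 5]])
        report = per_class_metrics(cm)
        np.testing.assert_array_equal(report.confusion.sum(axis=1), [5, 9, 5])


class TestMacroAverage:
    def test_identical_values_pass_through(self):
        assert macro_average([0.7, 0.7, 0.7]) == pytest.approx(0.7)

    def test_mean_of_zero_and_one(self):
        assert macro_average([0.0, 1.0]) == pytest.approx(0.5)


class TestStratifiedCV:
    def test_separable_table_classified_perfectly(self):
        X, y, _ = generate_feature_table(
            SynthTableSpec(n_samples=100, n_features=6, n_informative=3, n_classes=2, effect_size=12.0, seed=0)
        )
        report = stratified_cv(X, y, ClassifierSpec("SVM"), k=5, seed=0)
        assert report.accuracy == 1.0

    def test_permuted_labels_score_near_chance(self):
        X, y, _ = generate_feature_table(
            SynthTableSpec(n_samples=400, n_features=8, n_informative=4, n_classes=4, effect_size=5.0, seed=1)
        )
        yp = np.random.default_rng(0).permutation(y)
        report = stratified_cv(X, yp, ClassifierSpec("SVM"), k=5, seed=0)
        assert abs(report.accuracy - 0.25) < 0.10

    def test_pooled_predictions_cover_each_sample_once(self):
        X, y, _ = generate_feature_table(SynthTableSpec(n_samples=60, n_features=4, n_informative=2, n_classes=3, seed=2))
        report = stratified_cv(X, y, ClassifierSpec("DT"), k=5, seed=0)
        assert report.confusion.sum() == 60
        np.testing.assert_array_equal(report.confusion.sum(axis=1), np.bincount(y))
        assert (report.fold_assignments >= 0).all()

    @pytest.mark.parametrize("kind", ["DT", "LD", "NB", "SVM", "KNN"])
    def test_all_classifier_kinds_run(self, kind):
        X, y, _ = generate_feature_table(
            SynthTableSpec(n_samples=80, n_features=5, n_informative=3, n_classes=2, effect_size=4.0, seed=3)
        )
        report = stratified_cv(X, y, ClassifierSpec(kind), k=4, seed=0)
        assert 0.5 <= report.accuracy <= 1.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown classifier"):
            ClassifierSpec("RandomForest")

    def test_fold_assignment_reproducible(self):
        X, y, _ = generate_feature_table(SynthTableSpec(n_samples=50, n_features=4, n_informative=2, n_classes=2, seed=4))
        a = stratified_cv(X, y, ClassifierSpec("KNN"), k=5, seed=9)
        b = stratified_cv(X, y, ClassifierSpec("KNN"), k=5, seed=9)
        np.testing.assert_array_equal(a.fold_assignments, b.fold_assignments)

    def test_auc_of_noise_features_near_half(self):
        # pure-noise features on balanced binary labels: OvR AUC ~ 0.5
        aucs = []
        for seed in range(5):
            X, y, _ = generate_feature_table(
                SynthTableSpec(n_samples=200, n_features=6, n_informative=0, n_classes=2, seed=seed)
            )
            report = stratified_cv(X, y, ClassifierSpec("LD"), k=5, seed=seed)
            aucs.append(report.auc_ovr["macro"])
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_small_class_reduces_fold_count_with_warning(self):
        X = np.random.default_rng(5).normal(size=(12, 3))
        y = np.array([0] * 9 + [1] * 3)
        with pytest.warns(UserWarning, match="reducing folds"):
            stratified_cv(X, y, ClassifierSpec("NB"), k=10, seed=0)


class TestRunPipeline:
    def test_feature_table_input_skips_extraction(self, trained_pipeline):
        _, labels, _, _, feats = trained_pipeline
        cfg = PipelineConfig(cv_folds=5, seed=0)
        report = run_pipeline(feats, labels, cfg)
        assert len(report.classes) == 8
        assert set(report.per_class) == {"sensitivity", "specificity", "precision", "f_score"}

    def test_paper_mode_smoke_on_phantoms(self):
        imgs, labels = generate_phantom_images(SynthImageSpec(n_per_class=10, image_size=32, seed=3))
        mcfg = ModelConfig(n_residual_blocks=1, block_filters=(6,), stem_filters=4,
                           lstm_units=8, fc1_width=24, n_classes=8, input_size=32)
        tcfg = TrainConfig(batch_size=16, learning_rate=0.01, max_epochs=6, seed=0)
        cfg = PipelineConfig(mode="paper", cv_folds=5, seed=0, model_config=mcfg, train_config=tcfg)
        report = run_pipeline(imgs, labels, cfg)
        assert report.confusion.sum() == 80
        assert len(report.per_class["f_score"]) == 8

    def test_honest_mode_does_not_beat_paper_mode(self):
        # leakage direction: training the extractor on all data before CV can
        # only help the classifier, so paper-mode accuracy >= honest-mode
        # accuracy on average
        imgs, labels = generate_phantom_images(SynthImageSpec(n_per_class=10, image_size=32, seed=4))
        mcfg = ModelConfig(n_residual_blocks=1, block_filters=(6,), stem_filters=4,
                           lstm_units=8, fc1_width=24, n_classes=8, input_size=32)
        tcfg = TrainConfig(batch_size=16, learning_rate=0.01, max_epochs=6, seed=0)
        paper, honest = [], []
        for seed in range(3):
            pc = PipelineConfig(mode="paper", cv_folds=3, seed=seed, model_config=mcfg, train_config=tcfg)
            hc = PipelineConfig(mode="honest", cv_folds=3, seed=seed, model_config=mcfg, train_config=tcfg)
            paper.append(run_pipeline(imgs, labels, pc).accuracy)
            honest.append(run_pipeline(imgs, labels, hc).accuracy)
        assert np.mean(honest) <= np.mean(paper) + 0.05

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            PipelineConfig(mode="optimistic")
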