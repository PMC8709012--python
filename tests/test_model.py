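"""Architecture assembly, sequence folding, training and feature extraction."""

import numpy as np
import pytest

from fundusnet.model import (
    ConfigurationError,
    Model,
    ModelConfig,
    TrainConfig,
    build_model,
    extract_deep_features,
    fold_to_sequence,
    refold_from_sequence,
    train_model,
)


class TestBuildModel:
    def test_default_config_yields_350_features_from_125px_input(self):
        model = build_model(ModelConfig(), seed=0)
        x = np.random.default_rng(0).random((1, 125, 125, 3))
        feats = model.fc1_activations(x)
        assert feats.shape == (1, 350)

    def test_variants_differ_only_in_skip_and_lstm_presence(self):
        kw = dict(n_residual_blocks=2, block_filters=(4, 4), stem_filters=3,
                  lstm_units=5, fc1_width=6, n_classes=2, input_size=16)
        cnn = build_model(ModelConfig(variant="cnn", **kw))
        rcnn = build_model(ModelConfig(variant="rcnn", **kw))
        rcnn_lstm = build_model(ModelConfig(variant="rcnn_lstm", **kw))
        assert all(not b.use_skip for b in cnn.blocks)
        assert all(b.use_skip for b in rcnn.blocks)
        assert cnn.lstm is None and rcnn.lstm is None
        assert rcnn_lstm.lstm is not None

    def test_parameter_count_matches_closed_form(self):
        cfg = ModelConfig(
            n_residual_blocks=1, block_filters=(4,), stem_filters=4,
            lstm_units=8, fc1_width=16, n_classes=2, input_size=32,
        )
        model = build_model(cfg)
        # arithmetic oracle from the layer shapes:
        # stem conv 3x3x3 -> 4 filters, plus BN affine (2 per channel)
        stem = 3 * 3 * 3 * 4 + 4 + 2 * 4
        # block: two 3x3 convs 4->4 with bias, two BN affines; no projection
        block = 2 * (3 * 3 * 4 * 4 + 4) + 2 * (2 * 4)
        # 32 -> 16 (stem, stride 2) -> 16 (single block, stride 1)
        seq_dim = 16 * 4
        lstm = 4 * (8 * (8 + seq_dim)) + 4 * 8
        fc1 = 8 * 16 + 16
        head = 16 * 2 + 2
        assert model.n_params == stem + block + lstm + fc1 + head

    def test_too_small_input_reports_minimum(self):
        with pytest.raises(ConfigurationError, match="minimum input size"):
            build_model(ModelConfig(input_size=8))

    def test_softmax_head_rows_sum_to_one(self):
        model = build_model(ModelConfig(
            n_residual_blocks=1, block_filters=(4,), stem_filters=3,
            lstm_units=5, fc1_width=6, n_classes=4, input_size=16))
        probs = model.predict_proba(np.random.default_rng(1).random((3, 16, 16, 3)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestFoldToSequence:
    def test_two_by_two_single_channel(self):
        fmap = np.array([[[1.0], [2.0]], [[3.0], [4.0]]])  # 2x2x1
        seq = fold_to_sequence(fmap)
        np.testing.assert_array_equal(seq, [[1, 2], [3, 4]])

    def test_single_pixel_map_gives_one_timestep(self):
        fmap = np.arange(5.0).reshape(1, 1, 5)
        seq = fold_to_sequence(fmap)
        assert seq.shape == (1, 5)
        np.testing.assert_array_equal(seq[0], np.arange(5.0))

    def test_round_trip_is_identity(self):
        rng = np.random.default_rng(2)
        fmap = rng.normal(size=(4, 6, 5, 3))
        np.testing.assert_array_equal(refold_from_sequence(fold_to_sequence(fmap), 5, 3), fmap)


SMALL = dict(n_residual_blocks=1, block_filters=(6,), stem_filters=4,
             lstm_units=8, fc1_width=12, n_classes=2, input_size=32)


class TestTraining:
    def _two_class_set(self, n=40):
        from fundusnet.synthdata import SynthImageSpec, generate_phantom_images

        return generate_phantom_images(
            SynthImageSpec(n_per_class=n, class_names=("Normal", "Cataract"), image_size=32, seed=1)
        )

    def test_zero_epochs_is_a_no_op(self):
        imgs, labels = self._two_class_set(4)
        model = build_model(ModelConfig(**SMALL), seed=0)
        before = [p.value.copy() for p in model.params()]
        model, history = train_model(model, imgs, labels, TrainConfig(max_epochs=0))
        assert history.loss == [] and history.accuracy == []
        for p, b in zip(model.params(), before):
            np.testing.assert_array_equal(p.value, b)

    def test_single_class_rejected(self):
        imgs, _ = self._two_class_set(3)
        model = build_model(ModelConfig(**SMALL))
        with pytest.raises(ValueError, match="two classes"):
            train_model(model, imgs, np.array(["A"] * len(imgs)), TrainConfig(max_epochs=1))

    def test_obvious_two_class_problem_is_learned(self):
        imgs, labels = self._two_class_set(40)
        model = build_model(ModelConfig(**SMALL), seed=0)
        tc = TrainConfig(batch_size=16, learning_rate=0.01, max_epochs=30, seed=0)
        model, history = train_model(model, imgs, labels, tc)
        assert history.accuracy[-1] >= 0.95

    def test_loss_decreases_on_separable_toy(self):
        imgs, labels = self._two_class_set(20)
        model = build_model(ModelConfig(**SMALL), seed=0)
        tc = TrainConfig(batch_size=40, learning_rate=0.003, max_epochs=12, seed=0)
        _, history = train_model(model, imgs, labels, tc)
        # smoke property: clear downward trend for a small learning rate
        assert history.loss[-1] < history.loss[0]

    def test_training_is_deterministic_given_seed(self):
        imgs, labels = self._two_class_set(6)
        runs = []
        for _ in range(2):
            model = build_model(ModelConfig(**SMALL), seed=3)
            model, history = train_model(
                model, imgs, labels, TrainConfig(batch_size=8, max_epochs=2, seed=3)
            )
            runs.append((history.loss, [p.value.copy() for p in model.params()]))
        assert runs[0][0] == runs[1][0]
        for a, b in zip(runs[0][1], runs[1][1]):
            np.testing.assert_array_equal(a, b)


class TestExtractDeepFeatures:
    def test_row_count_and_width(self, trained_pipeline):
        imgs, _, model, _, feats = trained_pipeline
        assert feats.shape == (len(imgs), model.config.fc1_width)

    def test_empty_input_gives_zero_rows(self):
        model = build_model(ModelConfig(**SMALL))
        out = extract_deep_features(model, np.zeros((0, 32, 32, 3)))
        assert out.matrix.shape == (0, SMALL["fc1_width"])

    def test_extraction_is_deterministic(self, trained_pipeline):
        imgs, _, model, _, feats = trained_pipeline
        again = extract_deep_features(model, imgs[:8]).matrix
        np.testing.assert_array_equal(again, feats[:8])

    def test_mismatched_size_resized_with_warning(self):
        model = build_model(ModelConfig(**SMALL))
        with pytest.warns(UserWarning, match="resizing"):
            out = extract_deep_features(model, np.random.default_rng(0).random((2, 20, 20, 3)))
        assert out.matrix.shape == (2, SMALL["fc1_width"])


class TestCheckpointRoundTrip:
    def test_save_load_preserves_predictions(self, tmp_path, trained_pipeline):
        imgs, _, model, _, _ = trained_pipeline
        model.save(tmp_path / "ckpt")
        loaded = Model.load(tmp_path / "ckpt")
        np.testing.assert_allclose(
            loaded.predict_proba(imgs[:4]), model.predict_proba(imgs[:4]), atol=1e-12
        )
        assert list(loaded.classes_) == list(model.classes_)
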