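import numpy as np
import pytest

from bloomsat import detector, synthetic


def _tiny_config(**kw):
    defaults = dict(n_blocks=2, filters_per_block=(4, 8), dense_units=16,
                    dropout_rate=0.0, input_side=32, epochs=3,
                    learning_rate=1e-3, seed=0)
    defaults.update(kw)
    return detector.DetectorConfig(**defaults)


class TestBuildDetector:
    def test_parameter_count_matches_hand_computation(self):
        model = detector.build_detector(_tiny_config())
        # conv1 (3*3*4+1)*4, conv2 (3*3*4+1)*8, dense (8*8*8+1)*16,
        # head (16+1)*2
        expected = 148 + 296 + (8 * 8 * 8 + 1) * 16 + 34
        assert model.n_params == expected
        assert model.n_trainable_params == expected

    def test_softmax_output_is_probability(self, rng):
        model = detector.build_detector(_tiny_config())
        x = rng.integers(0, 255, (3, 32, 32, 4)).astype(np.uint8)
        probs = model.predict_proba(x)
        assert probs.shape == (3, 2)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_default_config_accepts_136_patch(self, rng):
        model = detector.build_detector(detector.DetectorConfig())
        patch = rng.integers(0, 255, (1, 136, 136, 4)).astype(np.uint8)
        probs = model.predict_proba(patch)
        assert probs.shape == (1, 2)

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            detector.build_detector(detector.DetectorConfig(
                n_blocks=5, input_side=16))

    def test_shape_mismatch_rejected(self, rng):
        model = detector.build_detector(_tiny_config())
        with pytest.raises(ValueError):
            model.predict_proba(rng.random((2, 16, 16, 4)))


class TestAugmentPatch:
    def test_double_flip_is_identity(self, rng):
        class AlwaysFlip:
            def random(self):
                return 0.0  # < 0.5 on both draws -> flip both axes

        patch = rng.integers(0, 255, (8, 8, 4))
        once = detector.augment_patch(patch, AlwaysFlip())
        twice = detector.augment_patch(once, AlwaysFlip())
        assert not np.array_equal(once, patch)
        assert np.array_equal(twice, patch)

    def test_forced_no_flip_is_identity(self, rng):
        patch = rng.integers(0, 255, (8, 8, 4))

        class NoFlip:
            def random(self):
                return 0.9  # >= 0.5 on both draws -> no flip

        assert np.array_equal(detector.augment_patch(patch, NoFlip()), patch)

    def test_flip_states_uniform(self):
        # marker patch identifying each of the 4 flip states
        patch = np.zeros((2, 2, 1))
        patch[0, 0] = 1
        rng = np.random.default_rng(123)
        counts = np.zeros(4)
        n = 10_000
        for _ in range(n):
            out = detector.augment_patch(patch, rng)
            counts[int(np.argmax(out.ravel()))] += 1
        sd = np.sqrt(n * 0.25 * 0.75)
        assert np.all(np.abs(counts - n / 4) <= 3 * sd)


class TestClassWeights:
    def test_full_corpus_ratio(self):
        ratio = detector.class_weight_ratio(123_071, 35_541)
        assert round(ratio, 1) == 3.5

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            detector.class_weight_ratio(100, 0)


class TestTrainingHistory:
    def test_best_epoch_is_argmax(self):
        hist = detector.TrainingHistory(
            loss=[1.0, 0.5, 0.6],
            weighted_accuracy=[0.8, 0.9, 0.85])
        assert hist.best_epoch == 2
        assert hist.best_weighted_accuracy == 0.9


class TestPredict:
    def test_tie_goes_to_presence(self, rng):
        model = detector.build_detector(_tiny_config())
        # zero the head: logits are (0, 0) -> probabilities exactly 0.5
        head = model.net.layers[-1]
        head.params["W"][:] = 0
        head.params["b"][:] = 0
        x = rng.integers(0, 255, (4, 32, 32, 4)).astype(np.uint8)
        assert np.all(detector.predict_patches(model, x) == 1)

    def test_batch_order_irrelevant(self, patch_dataset):
        X, _ = patch_dataset
        model = detector.build_detector(_tiny_config())
        perm = np.random.default_rng(1).permutation(50)
        preds = detector.predict_patches(model, X[:50])
        assert np.array_equal(detector.predict_patches(model, X[:50][perm]),
                              preds[perm])

    def test_single_class_training_rejected(self, patch_dataset):
        X, _ = patch_dataset
        model = detector.build_detector(_tiny_config(epochs=1))
        with pytest.raises(ValueError):
            detector.train_detector(model, X[:10], np.zeros(10, int))


class TestTrainingReproducibility:
    def test_same_seed_same_weights(self, patch_dataset):
        X, y = patch_dataset
        runs = []
        for _ in range(2):
            model = detector.build_detector(_tiny_config(epochs=2))
            model, hist = detector.train_detector(model, X[:120], y[:120])
            runs.append((model.net.get_weights(), hist.loss))
        assert runs[0][1] == runs[1][1]
        for a, b in zip(runs[0][0], runs[1][0]):
            assert np.array_equal(a, b)


class TestColorOracle:
    def _green(self, side=32):
        patch = np.zeros((side, side, 4), np.uint8)
        patch[..., 0] = 50
        patch[..., 1] = 120
        patch[..., 2] = 40
        return patch

    def test_uniform_green_is_absence(self):
        assert detector.reference_color_detector(self._green()) == 0

    def test_clump_at_threshold(self):
        patch = self._green()
        patch[10:13, 10:13, 0] = 200
        patch[10:13, 10:13, 2] = 200
        assert detector.reference_color_detector(patch, min_clump=9) == 1
        assert detector.reference_color_detector(patch, min_clump=10) == 0

    def test_border_clump_ignored(self):
        """Labels apply to the core only: a clump wholly inside the 4-px
        border must not flip the label."""
        patch = self._green()
        patch[0:3, :, 0] = 200
        patch[0:3, :, 2] = 200
        assert detector.reference_color_detector(patch, min_clump=9) == 0

    def test_diagonal_pixels_not_4connected(self):
        patch = self._green()
        for i in range(10, 16):  # 6 diagonal singletons
            patch[i, i, 0] = 200
            patch[i, i, 2] = 200
        assert detector.reference_color_detector(patch, min_clump=2) == 0

    def test_soil_confounder_rejected(self):
        patch = self._green()
        patch[8:20, 8:20, 0] = 180   # red up, blue below green
        patch[8:20, 8:20, 2] = 90
        assert detector.reference_color_detector(patch) == 0


def test_oracle_matches_labels_on_synthetic_patches(patch_dataset):
    X, y = patch_dataset
    pred = np.array([detector.reference_color_detector(p) for p in X])
    assert (pred == y).mean() >= 0.99
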