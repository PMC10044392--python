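"""Segmentation estimator: architecture, training, inference, persistence."""

from __future__ import annotations

import numpy as np
import pytest

from woundseg._nn import UNetCore, focal_loss_and_grad
from woundseg.model import (
    BackboneSpec,
    ModelState,
    TrainingConfig,
    UNetSegmenter,
    augment_pair,
    build_model,
    predict_masks,
    reset_weights,
)


class TestArchitecture:
    def test_output_shape_and_range(self):
        state = build_model(BackboneSpec("tiny"), seed=0)
        est = UNetSegmenter().load_state(state)
        rng = np.random.default_rng(0)
        X = rng.integers(0, 256, size=(2, 64, 64, 3), dtype=np.uint8)
        probs = est.predict_proba(X)
        assert probs.shape == (2, 64, 64)
        assert probs.min() >= 0.0 and probs.max() <= 1.0

    def test_seeded_init_is_reproducible(self):
        a = build_model(BackboneSpec("tiny"), seed=3)
        b = build_model(BackboneSpec("tiny"), seed=3)
        for k in a.weights:
            assert np.array_equal(a.weights[k], b.weights[k])

    def test_parameter_count_ordering(self):
        counts = {
            name: UNetSegmenter().load_state(build_model(BackboneSpec(name))).n_parameters_
            for name in ("tiny", "small", "large")
        }
        assert counts["tiny"] < counts["small"] < counts["large"]

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError, match="unknown backbone"):
            BackboneSpec("resnet152")

    def test_zero_logit_model_predicts_all_ones_at_half(self):
        state = build_model(BackboneSpec("tiny"), seed=0)
        for k in state.weights:
            if k.startswith("head"):
                state.weights[k][:] = 0.0
        est = UNetSegmenter(threshold=0.5).load_state(state)
        X = np.zeros((1, 64, 64, 3), dtype=np.uint8)
        # sigmoid(0) = 0.5 and binarization is inclusive (>=)
        assert est.predict(X).all()


class TestAugmentation:
    def test_involution_and_area_conservation(self, blob_mask):
        img = np.random.default_rng(0).integers(0, 256, size=(*blob_mask.shape, 3),
                                                dtype=np.uint8)
        area = blob_mask.sum()
        rng = np.random.default_rng(1)
        for _ in range(20):
            im2, m2 = augment_pair(img, blob_mask, rng)
            assert m2.sum() == area
            # the same flip was applied to both rasters
            red_in = img[..., 0][blob_mask.astype(bool)].sum()
            assert im2[..., 0][m2.astype(bool)].sum() == red_in

    def test_flip_combination_frequencies(self):
        img = np.arange(16, dtype=np.uint8).reshape(4, 4, 1).repeat(3, axis=2)
        mask = (np.arange(16).reshape(4, 4) % 2).astype(np.uint8)
        rng = np.random.default_rng(0)
        variants = {
            "identity": img,
            "h": img[:, ::-1],
            "v": img[::-1, :],
            "hv": img[::-1, ::-1],
        }
        counts = dict.fromkeys(variants, 0)
        for _ in range(1000):
            im2, _ = augment_pair(img, mask, rng)
            matches = [k for k, v in variants.items() if np.array_equal(im2, v)]
            assert len(matches) == 1
            counts[matches[0]] += 1
        for count in counts.values():
            assert 200 <= count <= 300  # 0.25 +/- 0.05

    def test_shape_mismatch(self, blob_mask):
        with pytest.raises(ValueError):
            augment_pair(np.zeros((4, 4, 3)), blob_mask, np.random.default_rng(0))


class TestTraining:
    def test_loss_decreases(self, trained_easy_model):
        est, _, _ = trained_easy_model
        assert est.history_["loss"][-1] < est.history_["loss"][0]

    def test_holdout_f1_on_easy_regime(self, trained_easy_model):
        est, X, y = trained_easy_model
        assert est.score(X[30:], y[30:]) >= 0.9

    def test_identical_seeds_identical_history(self, easy_dataset):
        samples, _ = easy_dataset
        X = np.stack([s.pixels for s in samples[:10]])
        y = np.stack([s.truth_mask for s in samples[:10]])
        hists = []
        for _ in range(2):
            est = UNetSegmenter(epochs=3, learning_rate=1e-3, seed=5)
            est.fit(X, y)
            hists.append(est.history_["loss"])
        assert hists[0] == hists[1]

    def test_empty_or_unlabeled_training_set(self):
        est = UNetSegmenter(epochs=1)
        with pytest.raises(ValueError):
            est.fit(np.zeros((0, 64, 64, 3)), np.zeros((0, 64, 64)))
        with pytest.raises(ValueError):
            est.fit(np.zeros((2, 64, 64, 3)), np.zeros((3, 64, 64)))

    def test_first_epoch_matches_half_cross_entropy_scaling(self):
        # focal loss with gamma=0, alpha=0.5 is exactly half the BCE for
        # the same logits, so the recorded first losses differ by 2x
        rng = np.random.default_rng(0)
        z = rng.normal(size=(4, 16, 16))
        y = rng.integers(0, 2, size=(4, 16, 16)).astype(np.float64)
        focal, _ = focal_loss_and_grad(y, z, alpha=0.5, gamma=0.0)
        p = np.clip(1 / (1 + np.exp(-z)), 1e-7, 1 - 1e-7)
        bce = float(np.mean(-y * np.log(p) - (1 - y) * np.log1p(-p)))
        assert focal == pytest.approx(0.5 * bce, abs=1e-9)


class TestPersistenceAndReset:
    def test_save_load_round_trip_bit_exact(self, trained_easy_model, tmp_path):
        est, X, _ = trained_easy_model
        est.state_.save(tmp_path / "model")
        loaded = ModelState.load(tmp_path / "model")
        est2 = UNetSegmenter().load_state(loaded)
        p1 = est.predict_proba(X[:4])
        p2 = est2.predict_proba(X[:4])
        assert np.array_equal(p1, p2)

    def test_reset_restores_pretrained_predictions(self, trained_easy_model):
        est, X, _ = trained_easy_model
        pretrained = build_model(BackboneSpec("tiny"), seed=9, provenance="pre")
        restored = reset_weights(est.state_, pretrained)
        a = predict_masks(restored, X[:4])
        b = predict_masks(pretrained, X[:4])
        assert np.array_equal(a, b)

    def test_reset_is_idempotent(self):
        pre = build_model(BackboneSpec("tiny"), seed=1)
        once = reset_weights(build_model(BackboneSpec("tiny"), seed=2), pre)
        twice = reset_weights(once, pre)
        for k in pre.weights:
            assert np.array_equal(once.weights[k], twice.weights[k])

    def test_reset_requires_matching_spec(self):
        a = build_model(BackboneSpec("tiny"), seed=0)
        b = build_model(BackboneSpec("small"), seed=0)
        with pytest.raises(ValueError, match="backbone"):
            reset_weights(a, b)

    def test_pretrained_start_is_bit_identical(self):
        """A round's model starts exactly from the pretrained weights."""
        pre = build_model(BackboneSpec("tiny"), seed=4)
        est = UNetSegmenter(pretrained=pre, seed=99)
        core = est._build_core()
        for k, v in pre.weights.items():
            assert np.array_equal(core.params[k], v)

    def test_predict_without_weights_raises(self):
        with pytest.raises(RuntimeError, match="weights"):
            UNetSegmenter().predict(np.zeros((1, 64, 64, 3), dtype=np.uint8))


class TestResizePolicy:
    def test_prediction_at_original_resolution(self):
        state = build_model(BackboneSpec("tiny"), seed=0)
        est = UNetSegmenter().load_state(state)
        X = np.zeros((1, 100, 80, 3), dtype=np.uint8)
        assert est.predict(X).shape == (1, 100, 80)

    def test_inference_is_deterministic(self, trained_easy_model):
        est, X, _ = trained_easy_model
        assert np.array_equal(est.predict(X[:3]), est.predict(X[:3]))
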