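"""Residual U-Net building blocks, dice loss, training mechanics."""

import numpy as np
import pytest

from noduleseg.metrics import dsc
from noduleseg.nn import (
    AXIAL_SPEC,
    CORONAL_SAGITTAL_SPEC,
    NetworkSpec,
    ResidualUnit,
    TrainConfig,
    as_segmenter,
    build_network,
    dice_loss,
    dice_loss_grad,
    load_model,
    save_model,
    train,
)
from noduleseg.volume_io import MaskVolume


class TestResidualUnit:
    def test_identity_path_with_zero_conv_weights(self, rng):
        unit = ResidualUnit(4, 4, stride=1, rng=rng)
        unit.conv1.W[...] = 0.0
        unit.conv2.W[...] = 0.0
        x = rng.normal(size=(2, 8, 8, 4)).astype(np.float32)
        np.testing.assert_allclose(unit.forward(x), x, atol=1e-6)

    def test_stride_two_halves_resolution(self, rng):
        unit = ResidualUnit(1, 8, stride=2, rng=rng)
        out = unit.forward(rng.normal(size=(1, 128, 128, 1)).astype(np.float32))
        assert out.shape == (1, 64, 64, 8)

    def test_gradient_reaches_input(self, rng):
        unit = ResidualUnit(2, 3, stride=1, rng=rng)
        x = rng.normal(size=(2, 6, 6, 2)).astype(np.float32)
        out = unit.forward(x, train=True)
        dx = unit.backward(np.ones_like(out))
        assert dx.shape == x.shape
        assert np.isfinite(dx).all() and np.abs(dx).sum() > 0

    def test_invalid_stride_rejected(self, rng):
        with pytest.raises(ValueError):
            ResidualUnit(1, 2, stride=3, rng=rng)


class TestBuildNetwork:
    def test_axial_spec_counts(self):
        assert AXIAL_SPEC.n_levels == 9
        assert AXIAL_SPEC.n_conv_layers == 19
        assert CORONAL_SAGITTAL_SPEC.n_levels == 7
        assert CORONAL_SAGITTAL_SPEC.n_conv_layers == 15

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec("bad", (30, 30), (8, 16, 32))

    def test_output_is_probability(self, rng):
        model = build_network(NetworkSpec("t", (16, 16), (4, 8)), seed=0)
        out = model.forward(rng.random((2, 16, 16, 1)).astype(np.float32))
        assert out.shape == (2, 16, 16, 1)
        assert (out > 0).all() and (out < 1).all()

    def test_wrong_input_shape_rejected(self, rng):
        model = build_network(NetworkSpec("t", (16, 16), (4, 8)), seed=0)
        with pytest.raises(ValueError):
            model.forward(rng.random((1, 8, 8, 1)))


class TestDiceLoss:
    def test_perfect_prediction_zero_loss(self, rng):
        t = (rng.random((3, 8, 8, 1)) > 0.5).astype(np.float32)
        assert dice_loss(t, t) == pytest.approx(0.0, abs=1e-5)

    def test_complement_prediction_unit_loss(self, rng):
        t = (rng.random((3, 8, 8, 1)) > 0.5).astype(np.float32)
        assert dice_loss(1 - t, t) == pytest.approx(1.0, abs=1e-5)

    def test_matches_brute_force_sum(self):
        """Uniform 0.5 prediction vs half-foreground truth, hand-summed."""
        pred = np.full((1, 4, 4), 0.5)
        truth = np.zeros((1, 4, 4))
        truth[0, :2, :] = 1.0
        # brute-force per-pixel evaluation of 1 - 2*sum(p*t)/(sum p + sum t + eps)
        inter = sum(
            pred[0, i, j] * truth[0, i, j] for i in range(4) for j in range(4)
        )
        denom = pred.sum() + truth.sum() + 1e-7
        assert dice_loss(pred, truth) == pytest.approx(1 - 2 * inter / denom, abs=1e-12)

    def test_equals_one_minus_dsc_on_binary(self, rng):
        a = (rng.random((4, 6, 5)) > 0.5).astype(np.uint8)
        b = (rng.random((4, 6, 5)) > 0.5).astype(np.uint8)
        ma = MaskVolume(a.copy(), (1, 1, 1))
        mb = MaskVolume(b.copy(), (1, 1, 1))
        loss = dice_loss(a[None].astype(float), b[None].astype(float))
        assert loss == pytest.approx(1.0 - dsc(ma, mb), abs=1e-6)

    def test_gradient_matches_numeric(self, rng):
        pred = rng.uniform(0.1, 0.9, size=(2, 3, 3))
        truth = (rng.random((2, 3, 3)) > 0.5).astype(float)
        grad = dice_loss_grad(pred, truth)
        for k in rng.integers(0, pred.size, 6):
            eps = 1e-6
            old = pred.ravel()[k]
            pred.ravel()[k] = old + eps
            lp = dice_loss(pred, truth)
            pred.ravel()[k] = old - eps
            lm = dice_loss(pred, truth)
            pred.ravel()[k] = old
            assert grad.ravel()[k] == pytest.approx((lp - lm) / (2 * eps), rel=1e-3, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((1, 2, 2)), np.zeros((1, 3, 3)))


class TestEndToEndGradient:
    def test_network_gradient_matches_numeric(self, rng):
        """Full forward/backward through a small U-Net vs finite differences."""
        model = build_network(NetworkSpec("gc", (8, 8), (3, 4)), seed=1)
        x = rng.random((2, 8, 8, 1)).astype(np.float32)
        t = (rng.random((2, 8, 8, 1)) > 0.6).astype(np.float32)
        prob = model.forward(x, train=True)
        model.backward(dice_loss_grad(prob, t))
        params = model.params()
        checked = 0
        for pi in rng.choice(len(params), size=6, replace=False):
            value, grad = params[pi]
            k = int(rng.integers(0, value.size))
            ana = float(grad.ravel()[k])
            if abs(ana) < 1e-4:  # below float32 finite-difference noise
                continue
            eps = 1e-3
            old = value.ravel()[k]
            value.ravel()[k] = old + eps
            lp = dice_loss(model.forward(x, train=True), t)
            value.ravel()[k] = old - eps
            lm = dice_loss(model.forward(x, train=True), t)
            value.ravel()[k] = old
            num = (lp - lm) / (2 * eps)
            assert ana == pytest.approx(num, rel=0.05, abs=1e-4)
            checked += 1
        assert checked >= 2


class TestTraining:
    SPEC = NetworkSpec("t16", (16, 16), (4, 8))

    def _blobs(self, n, seed=0):
        from noduleseg.synthetic import generate_blob_patches

        return generate_blob_patches(n, self.SPEC.input_shape, seed=seed)

    def test_zero_learning_rate_keeps_weights(self):
        patches, masks = self._blobs(8)
        model = build_network(self.SPEC, seed=0)
        before = [v.copy() for v, _ in model.params()]
        train(model, patches, masks, TrainConfig(learning_rate=0.0, max_epochs=2, seed=0))
        for b, (v, _) in zip(before, model.params()):
            np.testing.assert_array_equal(b, v)

    def test_single_sample_overfits(self):
        patches, masks = self._blobs(6, seed=2)
        idx = int(np.argmax(masks.sum(axis=(1, 2))))
        p, m = patches[idx : idx + 1], masks[idx : idx + 1]
        model = build_network(self.SPEC, seed=0)
        cfg = TrainConfig(learning_rate=0.1, momentum=0.9, batch_size=1, max_epochs=60, seed=0)
        history = train(model, p, m, cfg)
        assert history.train_dsc[-1] > 0.95

    def test_training_reproducible_per_seed(self):
        patches, masks = self._blobs(16, seed=3)
        weights = []
        for _ in range(2):
            model = build_network(self.SPEC, seed=5)
            train(model, patches, masks,
                  TrainConfig(learning_rate=0.05, momentum=0.9, max_epochs=3, seed=5))
            weights.append(np.concatenate([v.ravel() for v, _ in model.params()]))
        np.testing.assert_array_equal(weights[0], weights[1])

    def test_empty_dataset_rejected(self):
        model = build_network(self.SPEC, seed=0)
        with pytest.raises(ValueError):
            train(model, np.empty((0, 16, 16)), np.empty((0, 16, 16)), TrainConfig())


class TestAsSegmenter:
    class FakeModel:
        """Model stub emitting a constant probability."""

        def __init__(self, prob, shape=(16, 16)):
            from noduleseg.nn.resunet import NetworkSpec

            self.spec = NetworkSpec("fake", shape, (4, 8))
            self.prob = prob

        def forward(self, x, train=False):
            return np.full(x.shape, self.prob, dtype=np.float32)

    def test_above_threshold_all_ones(self):
        seg = as_segmenter(self.FakeModel(0.9), threshold=0.5)
        out = seg(np.zeros((16, 16), np.float32))
        assert out.shape == (16, 16) and out.all()

    def test_threshold_one_empty(self):
        seg = as_segmenter(self.FakeModel(0.9), threshold=1.0)
        assert seg(np.zeros((16, 16), np.float32)).sum() == 0

    def test_resizes_back_to_patch_shape(self):
        seg = as_segmenter(self.FakeModel(0.9), threshold=0.5)
        out = seg(np.zeros((7, 9), np.float32))
        assert out.shape == (7, 9) and out.all()


class TestCheckpointing:
    def test_save_load_round_trip(self, tmp_path, rng):
        model = build_network(NetworkSpec("t", (16, 16), (4, 8)), seed=2)
        x = rng.random((1, 16, 16, 1)).astype(np.float32)
        before = model.forward(x)
        save_model(model, str(tmp_path / "ckpt"))
        loaded = load_model(str(tmp_path / "ckpt"))
        np.testing.assert_allclose(loaded.forward(x), before, atol=1e-7)
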