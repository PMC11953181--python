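"""Loss closed forms, augmentation behaviour and the training loop."""

import numpy as np
import pytest

from canalseg import (
    AugmentParams,
    TrainingConfig,
    augment,
    consistency_loss,
    supervised_loss,
    train,
)
from canalseg.nn import DualDecoderUNet, DualDecoderUNetConfig, SegmentationOutput


def _output(pa, pb):
    return SegmentationOutput(probs={"A": pa, "B": pb}, logits={})


class TestSupervisedLoss:
    def test_uniform_prediction_is_ln2(self):
        """0.5/0.5 prediction on any binary label: pixel-averaged CE is
        exactly ln 2 per decoder."""
        p = np.full((1, 4, 4, 2), 0.5, np.float32)
        y = np.zeros((1, 4, 4), np.int64)
        y[0, :2] = 1
        loss = supervised_loss(_output(p, p), y)
        assert loss == pytest.approx(2.0 * np.log(2.0), abs=1e-6)

    def test_perfect_prediction_near_zero(self):
        y = (np.arange(16).reshape(1, 4, 4) % 2).astype(np.int64)
        onehot = np.eye(2, dtype=np.float32)[y]
        loss = supervised_loss(_output(onehot, onehot), y)
        assert 0.0 <= loss <= 2.0 * 1e-6

    def test_pixel_permutation_invariant(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet([1, 1], size=(1, 4, 4)).astype(np.float32)
        y = (rng.random((1, 4, 4)) > 0.5).astype(np.int64)
        perm = rng.permutation(16)
        p2 = p.reshape(1, 16, 2)[:, perm].reshape(1, 4, 4, 2)
        y2 = y.reshape(1, 16)[:, perm].reshape(1, 4, 4)
        a = supervised_loss(_output(p, p), y)
        b = supervised_loss(_output(p2, p2), y2)
        assert a == pytest.approx(b, rel=1e-6)

    def test_invalid_label_rejected(self):
        p = np.full((1, 4, 4, 2), 0.5, np.float32)
        with pytest.raises(ValueError, match="classes"):
            supervised_loss(_output(p, p), np.full((1, 4, 4), 3))


class TestConsistencyLoss:
    def test_identical_maps_zero(self):
        p = np.random.default_rng(1).dirichlet([1, 1], size=(2, 3, 3)).astype(np.float32)
        assert consistency_loss(p, p) == 0.0

    def test_opposite_onehot_maps(self):
        """All-(1,0) vs all-(0,1): every element differs by 1, so the
        element-mean of squared differences is exactly 1."""
        a = np.zeros((1, 2, 2, 2), np.float32)
        b = np.zeros((1, 2, 2, 2), np.float32)
        a[..., 0] = 1.0
        b[..., 1] = 1.0
        assert consistency_loss(a, b) == pytest.approx(1.0)

    def test_symmetric(self):
        rng = np.random.default_rng(2)
        a = rng.dirichlet([1, 1], size=(1, 4, 4)).astype(np.float32)
        b = rng.dirichlet([1, 1], size=(1, 4, 4)).astype(np.float32)
        assert consistency_loss(a, b) == pytest.approx(consistency_loss(b, a))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            consistency_loss(np.zeros((1, 2, 2, 2)), np.zeros((1, 3, 3, 2)))


class TestAugment:
    def test_identity_params_return_inputs(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(32, 32)).astype(np.float32)
        msk = (rng.random((32, 32)) > 0.5).astype(np.uint8)
        out_img, out_msk = augment(img, msk, AugmentParams.identity(), rng)
        np.testing.assert_array_equal(out_img, img)
        np.testing.assert_array_equal(out_msk, msk)

    def test_rotation_90_preserves_mask_area(self):
        """An axis-aligned square rotated 90 degrees keeps its pixel
        count up to boundary pixels (nearest-neighbour resampling)."""
        img = np.zeros((64, 64), np.float32)
        msk = np.zeros((64, 64), np.uint8)
        msk[20:40, 25:45] = 1
        params = AugmentParams(elastic_alpha_px=0.0, scale_range=(1.0, 1.0),
                               rotation_range_deg=(90.0, 90.0),
                               blur_sigma_range=(0.0, 0.0), noise_sd=0.0,
                               p_elastic=0.0, p_affine=1.0, p_blur=0.0, p_noise=0.0)
        _, out = augment(img, msk, params, np.random.default_rng(0))
        perimeter = 2 * (20 + 20)
        assert abs(int(out.sum()) - int(msk.sum())) <= perimeter
        assert set(np.unique(out)) <= {0, 1}

    def test_reproducible_given_seed(self):
        img = np.random.default_rng(3).normal(size=(32, 32)).astype(np.float32)
        msk = (img > 0).astype(np.uint8)
        params = AugmentParams()
        a = augment(img, msk, params, np.random.default_rng(42))
        b = augment(img, msk, params, np.random.default_rng(42))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_mask_stays_binary_under_full_suite(self):
        rng = np.random.default_rng(7)
        img = rng.normal(size=(32, 32)).astype(np.float32)
        msk = (rng.random((32, 32)) > 0.7).astype(np.uint8)
        params = AugmentParams(p_elastic=1.0, p_affine=1.0, p_blur=1.0, p_noise=1.0)
        for _ in range(5):
            _, out = augment(img, msk, params, rng)
            assert set(np.unique(out)) <= {0, 1}


def _toy_task(n, size=16, seed=0):
    """Tiny bright-disk segmentation task."""
    rng = np.random.default_rng(seed)
    data = []
    for _ in range(n):
        cy, cx = rng.uniform(5, size - 5, 2)
        r = rng.uniform(2.0, 4.0)
        yy, xx = np.mgrid[:size, :size]
        msk = ((yy - cy) ** 2 + (xx - cx) ** 2 <= r * r).astype(np.uint8)
        img = msk * 1.0 + rng.normal(0, 0.05, (size, size))
        data.append((img.astype(np.float32), msk))
    return data


class TestTrainLoop:
    def test_empty_labeled_set_rejected(self):
        model = DualDecoderUNet(DualDecoderUNetConfig(input_size=(16, 16), depth=2,
                                                      base_channels=2))
        with pytest.raises(ValueError, match="empty"):
            train(model, [], [], TrainingConfig(epochs=1))

    def test_lambda_zero_consistency_identically_zero(self):
        model = DualDecoderUNet(DualDecoderUNetConfig(input_size=(16, 16), depth=2,
                                                      base_channels=2), seed=0)
        data = _toy_task(4)
        _, hist = train(model, data, [], TrainingConfig(epochs=2, consistency_weight=0.0, seed=0))
        assert (hist.consistency_loss == 0.0).all()

    def test_lambda_zero_invariant_to_unlabeled_contents(self):
        cfg = DualDecoderUNetConfig(input_size=(16, 16), depth=2, base_channels=2)
        data = _toy_task(4)
        junk = [np.random.default_rng(9).normal(size=(16, 16)).astype(np.float32)]
        m1, h1 = train(DualDecoderUNet(cfg, seed=1), data, [],
                       TrainingConfig(epochs=2, consistency_weight=0.0, seed=5))
        m2, h2 = train(DualDecoderUNet(cfg, seed=1), data, junk,
                       TrainingConfig(epochs=2, consistency_weight=0.0, seed=5))
        for a, b in zip(m1.parameters(), m2.parameters()):
            np.testing.assert_array_equal(a.value, b.value)

    def test_reproducible_final_losses(self):
        cfg = DualDecoderUNetConfig(input_size=(16, 16), depth=2, base_channels=2)
        data = _toy_task(6)
        unl = [d[0] for d in _toy_task(6, seed=1)]
        _, h1 = train(DualDecoderUNet(cfg, seed=2), data, unl,
                      TrainingConfig(epochs=3, seed=7))
        _, h2 = train(DualDecoderUNet(cfg, seed=2), data, unl,
                      TrainingConfig(epochs=3, seed=7))
        assert h1.equals(h2)

    def test_memorization_loss_decreases(self):
        """Overfit sanity: supervised loss on a 4-slice memorisation
        task trends monotonically down (tail below early mean)."""
        cfg = DualDecoderUNetConfig(input_size=(16, 16), depth=2, base_channels=4)
        data = _toy_task(4, seed=3)
        _, hist = train(DualDecoderUNet(cfg, seed=3), data, [],
                        TrainingConfig(epochs=20, batch_size=4, seed=3))
        sup = hist.supervised_loss.to_numpy()
        assert sup[-1] < sup[0]
        assert sup[-5:].mean() < sup[:5].mean()
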