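"""Attention U-Net, focal loss, training and prediction contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lufor import nn
from lufor.model import (
    FocalLossParams,
    ModelConfig,
    TrainConfig,
    argmax_map,
    build_model,
    focal_loss,
    load_model,
    predict,
    save_model,
    train,
    NODATA_CLASS,
    _focal_loss_and_grad,
)
from lufor.preprocessing import make_image_stack


@pytest.fixture(scope="module")
def small_model():
    return build_model(ModelConfig(depth=2, base_filters=4, seed=0))


class TestArchitecture:
    def test_shape_preservation(self, small_model, rng):
        x = rng.uniform(size=(1, 7, 64, 64)).astype(np.float32)
        logits = small_model.net.forward(x, train=False)
        assert logits.shape == (1, 15, 64, 64)

    def test_deterministic_initialization(self, rng):
        x = rng.uniform(size=(2, 7, 32, 32)).astype(np.float32)
        y = rng.integers(0, 15, size=(2, 32, 32))
        losses = []
        for _ in range(2):
            m = build_model(ModelConfig(depth=2, base_filters=4, seed=99))
            logits = m.net.forward(x, train=False)
            p = FocalLossParams()
            l, _ = _focal_loss_and_grad(logits, y, p, p.alpha_vector(15), np.ones(15))
            losses.append(l)
        assert losses[0] == losses[1]

    def test_attention_maps_bounded(self, small_model, rng):
        x = rng.uniform(size=(1, 7, 32, 32)).astype(np.float32)
        small_model.net.forward(x, train=False)
        for gate in small_model.net.gates:
            att = gate.last_attention
            assert att is not None and att.min() >= 0.0 and att.max() <= 1.0

    def test_incompatible_dims_rejected(self, small_model, rng):
        with pytest.raises(ValueError):
            small_model.net.forward(rng.uniform(size=(1, 7, 30, 30)), train=False)
        with pytest.raises(ValueError):
            small_model.net.forward(rng.uniform(size=(1, 3, 32, 32)), train=False)


class TestFocalLoss:
    def test_zero_at_perfect_prediction(self):
        probs = np.zeros((4, 4, 3))
        t = np.arange(16).reshape(4, 4) % 3
        for i in range(3):
            probs[..., i] = t == i
        assert focal_loss(probs, t, FocalLossParams()) == 0.0

    def test_gamma_zero_is_cross_entropy(self, rng):
        probs = rng.dirichlet(np.ones(5), size=(6, 6))
        t = rng.integers(0, 5, size=(6, 6))
        fl = focal_loss(probs, t, FocalLossParams(gamma=0.0))
        pt = np.take_along_axis(probs, t[..., None], axis=-1)[..., 0]
        ce = -np.log(pt).mean()
        assert fl == pytest.approx(ce, abs=1e-6)

    def test_single_pixel_half_probability(self):
        probs = np.array([[[0.5, 0.5]]])
        t = np.array([[0]])
        val = focal_loss(probs, t, FocalLossParams(gamma=2.0))
        assert val == pytest.approx(0.25 * np.log(2), rel=1e-9)

    def test_ignored_pixels_contribute_zero(self, rng):
        probs = rng.dirichlet(np.ones(4), size=(5, 5))
        t = rng.integers(0, 4, size=(5, 5))
        base = focal_loss(probs, t, FocalLossParams())
        t2 = t.copy()
        t2[0] = -1  # ignoring a row changes the mean only via the denominator
        masked = focal_loss(probs, t2, FocalLossParams())
        manual = focal_loss(probs[1:], t[1:], FocalLossParams())
        assert masked == pytest.approx(manual)
        assert focal_loss(probs, np.full((5, 5), -1), FocalLossParams()) == 0.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(0.01, 0.99), st.floats(0.0, 4.0), st.floats(0.1, 4.0))
    def test_monotone_nonincreasing_in_gamma(self, p, g1, dg):
        probs = np.array([[[p, 1 - p]]])
        t = np.array([[0]])
        lo = focal_loss(probs, t, FocalLossParams(gamma=g1 + dg))
        hi = focal_loss(probs, t, FocalLossParams(gamma=g1))
        assert lo <= hi + 1e-12

    def test_rejects_out_of_range_targets(self, rng):
        probs = rng.dirichlet(np.ones(3), size=(2, 2))
        with pytest.raises(ValueError):
            focal_loss(probs, np.full((2, 2), 7), FocalLossParams())

    def test_gradient_matches_numeric(self):
        r = np.random.default_rng(3)
        logits = r.normal(size=(1, 4, 2, 2)).astype(np.float64)
        t = r.integers(0, 4, size=(1, 2, 2))
        params = FocalLossParams(gamma=2.0)
        a, w = params.alpha_vector(4), np.ones(4)
        _, dz = _focal_loss_and_grad(logits, t, params, a, w)
        eps = 1e-6
        for idx in [(0, 0, 0, 0), (0, 3, 1, 1), (0, 2, 0, 1)]:
            lp = logits.copy(); lp[idx] += eps
            lm = logits.copy(); lm[idx] -= eps
            num = (_focal_loss_and_grad(lp, t, params, a, w)[0]
                   - _focal_loss_and_grad(lm, t, params, a, w)[0]) / (2 * eps)
            assert num == pytest.approx(float(dz[idx]), abs=1e-5)


class TestTraining:
    def test_smoke_one_epoch(self, tiny_pools):
        model = build_model(ModelConfig(depth=2, base_filters=4, seed=1))
        tc = TrainConfig(epochs=1, batch_size=4, learning_rate=1e-3, patch_size=32, seed=1)
        model, hist = train(model, tiny_pools, tc)
        assert len(hist) == 1 and np.isfinite(hist[0])

    def test_deterministic_history(self, tiny_pools):
        tc = TrainConfig(epochs=2, batch_size=4, learning_rate=1e-3, patch_size=32, seed=5)
        hists = []
        for _ in range(2):
            model = build_model(ModelConfig(depth=2, base_filters=4, seed=5))
            _, hist = train(model, tiny_pools, tc)
            hists.append(hist)
        assert hists[0] == hists[1]

    def test_loss_decreases_on_clean_data(self):
        from lufor.scenes import CorruptionConfig, SceneConfig, generate_dataset

        pools = generate_dataset(4, SceneConfig(height=64, width=64, seed=8),
                                 CorruptionConfig(), annotated_fraction=0.5, seed=8)
        model = build_model(ModelConfig(depth=2, base_filters=8, seed=8))
        tc = TrainConfig(epochs=10, batch_size=8, learning_rate=2e-3, patch_size=32, seed=8)
        model, hist = train(model, pools, tc)
        assert hist[-1] < hist[0]

    def test_empty_pool_rejected(self):
        from lufor.pools import DataPools

        model = build_model(ModelConfig(depth=1, base_filters=4))
        with pytest.raises(ValueError):
            train(model, DataPools(), TrainConfig(epochs=1))


class TestPredict:
    def test_simplex_and_shape(self, small_model, scene_128):
        stack = make_image_stack(scene_128.bands)
        pm = predict(small_model, stack)
        assert pm.probs.shape == (128, 128, 15)
        assert np.allclose(pm.probs.sum(axis=-1), 1.0, atol=1e-5)

    def test_non_multiple_size_padded(self, small_model, rng):
        stack = rng.uniform(size=(50, 70, 7))
        pm = predict(small_model, stack)
        assert pm.probs.shape == (50, 70, 15)

    def test_argmax_and_tiebreak(self):
        probs = np.array([[[0.2, 0.8], [0.5, 0.5]]])
        out = argmax_map(probs)
        assert out[0, 0] == 1
        assert out[0, 1] == 0  # tie -> lowest class id

    def test_loss_mask_restriction(self):
        probs = np.full((4, 4, 3), 1 / 3)
        mask = np.zeros((4, 4), dtype=bool)
        out = argmax_map(probs, loss_mask=mask)
        assert (out == NODATA_CLASS).all()

    def test_checkpoint_roundtrip(self, small_model, rng, tmp_path):
        stack = rng.uniform(size=(32, 32, 7))
        before = predict(small_model, stack).probs
        save_model(small_model, tmp_path / "ckpt")
        loaded = load_model(tmp_path / "ckpt")
        after = predict(loaded, stack).probs
        assert np.allclose(before, after, atol=1e-6)
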