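"""Disentangled model: latent shapes, losses, determinism, disentanglement."""

import numpy as np
import pytest

from spiralcine import nn
from spiralcine.xsdnet import (LossBundle, ModelConfig, Segmentor, XSDNet,
                               _one_hot, cross_entropy, kl_divergence,
                               normalize_magnitude, soft_dice_loss)


@pytest.fixture(scope="module")
def tiny_model():
    return XSDNet(ModelConfig(base_width=8, unet_depth=2, seed=1))


@pytest.fixture(scope="module")
def test_image():
    rng = np.random.default_rng(0)
    return rng.uniform(0, 1, (1, 1, 32, 32)).astype(np.float32)


class TestLatents:
    def test_eight_anatomy_factors_softmaxed(self, tiny_model, test_image):
        f = tiny_model.encode_anatomy(nn.Tensor(test_image))
        assert f.data.shape[1] == 8
        assert np.abs(f.data.sum(axis=1) - 1).max() < 1e-5

    def test_binary_factors(self, tiny_model, test_image):
        out = tiny_model.forward(test_image)
        assert set(np.unique(out.factors_bin.data)).issubset({0.0, 1.0})

    def test_modality_vector_length_eight(self, tiny_model, test_image):
        out = tiny_model.forward(test_image)
        assert out.modality.mean.data.shape == (1, 8)
        assert out.modality.log_var.data.shape == (1, 8)
        assert np.all(np.isfinite(out.modality.log_var.data))

    def test_inference_sample_equals_mean(self, tiny_model, test_image):
        tiny_model.eval()
        out = tiny_model.forward(test_image)
        assert np.array_equal(out.modality.sample.data, out.modality.mean.data)
        tiny_model.train()

    def test_non_finite_input_rejected(self, tiny_model):
        bad = np.full((1, 1, 32, 32), np.nan, np.float32)
        with pytest.raises(ValueError):
            tiny_model.forward(bad)


class TestOutputs:
    def test_segmentation_probabilities(self, tiny_model, test_image):
        out = tiny_model.forward(test_image)
        p = out.seg_probs.data
        assert p.shape[1] == 4
        assert np.abs(p.sum(axis=1) - 1).max() < 1e-5
        labels = np.argmax(p, axis=1)
        assert set(np.unique(labels)).issubset({0, 1, 2, 3})

    def test_segmentor_has_three_conv_layers_before_classifier(self):
        seg = Segmentor()
        convs = [m for m in seg.body.layers if isinstance(m, nn.Conv2d)]
        assert len(convs) == 3

    def test_grids_preserved(self, tiny_model, test_image):
        out = tiny_model.forward(test_image)
        assert out.decoded.data.shape == test_image.shape
        assert out.refined.data.shape == test_image.shape
        assert out.factors_bin.data.shape[2:] == test_image.shape[2:]

    def test_inference_determinism(self, tiny_model, test_image):
        tiny_model.eval()
        a = tiny_model.forward(test_image)
        b = tiny_model.forward(test_image)
        assert np.array_equal(a.refined.data, b.refined.data)
        assert np.array_equal(a.seg_probs.data, b.seg_probs.data)
        tiny_model.train()

    def test_forward_under_one_second_at_128(self):
        import time
        model = XSDNet(ModelConfig(base_width=12, unet_depth=2, seed=0)).eval()
        x = np.random.default_rng(1).uniform(0, 1, (1, 1, 128, 128)) \
            .astype(np.float32)
        model.forward(x)  # warm up BLAS
        best = min(_timed(model, x) for _ in range(3))
        assert best < 1.0
        assert model.n_parameters() > 0

    def test_disentanglement_z_swap(self, tiny_model):
        """Swapping the modality vector changes the decoded image but the
        anatomy factors (not recomputed) keep their segmentation."""
        tiny_model.eval()
        rng = np.random.default_rng(5)
        x1 = rng.uniform(0, 1, (1, 1, 32, 32)).astype(np.float32)
        x2 = (0.3 * rng.uniform(0, 1, (1, 1, 32, 32))).astype(np.float32)
        o1, o2 = tiny_model.forward(x1), tiny_model.forward(x2)
        dec_swap = tiny_model.decoder(o1.factors_bin, o2.modality.sample)
        assert np.linalg.norm(dec_swap.data - o1.decoded.data) > 1e-6
        seg_again = tiny_model.segmentor(o1.factors_bin)
        assert np.array_equal(np.argmax(seg_again.data, axis=1),
                              np.argmax(o1.seg_probs.data, axis=1))
        tiny_model.train()


def _timed(model, x):
    import time
    t0 = time.perf_counter()
    model.forward(x)
    return time.perf_counter() - t0


class TestLosses:
    def test_kl_zero_for_standard_normal_posterior(self):
        mu = nn.Tensor(np.zeros((2, 8), np.float32))
        lv = nn.Tensor(np.zeros((2, 8), np.float32))
        assert float(kl_divergence(mu, lv).data) == pytest.approx(0.0)

    def test_kl_closed_form(self):
        mu = nn.Tensor(np.full((1, 8), 0.5, np.float32))
        lv = nn.Tensor(np.full((1, 8), -1.0, np.float32))
        expected = 0.5 * 8 * (0.25 + np.exp(-1.0) - 1 + 1.0)
        assert float(kl_divergence(mu, lv).data) == pytest.approx(expected, rel=1e-5)

    def test_dice_loss_perfect_and_complement(self):
        rng = np.random.default_rng(1)
        mask = (rng.uniform(size=(1, 8, 8)) > 0.5).astype(int)
        onehot = _one_hot(mask, 2)
        probs = nn.Tensor(onehot)
        assert float(soft_dice_loss(probs, onehot).data) == pytest.approx(0.0, abs=1e-4)
        flipped = _one_hot(1 - mask, 2)
        assert float(soft_dice_loss(nn.Tensor(flipped), onehot).data) == \
            pytest.approx(1.0, abs=1e-4)

    def test_cross_entropy_perfect_prediction(self):
        mask = np.zeros((1, 4, 4), int)
        onehot = _one_hot(mask, 4)
        ce = cross_entropy(nn.Tensor(onehot), onehot)
        assert float(ce.data) == pytest.approx(0.0, abs=1e-6)

    def test_loss_bundle_weighted_total(self, tiny_model, test_image):
        mask = np.zeros((1, 32, 32), int)
        out = tiny_model.forward(test_image)
        total, bundle = tiny_model.compute_losses(out, test_image, mask)
        w = tiny_model.config.weights()
        expected = (w["seg"] * bundle.seg + w["kl"] * bundle.kl +
                    w["modality"] * bundle.modality + w["recon"] * bundle.perceptual)
        assert bundle.total == pytest.approx(expected, rel=1e-5)
        assert bundle.kl >= 0

    def test_perceptual_zero_for_identical_images(self, tiny_model, test_image):
        feats_a = tiny_model.perceptual(nn.Tensor(test_image))
        feats_b = tiny_model.perceptual(nn.Tensor(test_image.copy()))
        for fa, fb in zip(feats_a, feats_b):
            assert np.array_equal(fa.data, fb.data)


class TestPersistence:
    def test_checkpoint_roundtrip(self, tmp_path, test_image):
        model = XSDNet(ModelConfig(base_width=8, unet_depth=2, seed=2))
        model.eval()
        ref = model.forward(test_image).refined.data
        path = str(tmp_path / "ckpt.npz")
        model.save(path)
        loaded = XSDNet.load(path).eval()
        out = loaded.forward(test_image).refined.data
        assert np.array_equal(ref, out)


class TestNormalization:
    def test_percentile_scaling(self):
        img = np.linspace(0, 200, 10_000).reshape(100, 100)
        out = normalize_magnitude(img)
        assert out.max() <= 1.0
        assert out.min() >= 0.0
        assert out.dtype == np.float32

    def test_complex_input_uses_magnitude(self):
        img = 1j * np.ones((8, 8))
        out = normalize_magnitude(img)
        assert np.allclose(out, 1.0)
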