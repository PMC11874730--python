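"""Disentangled joint reconstruction and segmentation model.

The model factorizes an undersampled interim image into two latents:

* an *anatomy* latent — eight spatial factor channels, binarized to
  Boolean maps, produced by a U-Net encoder with a channel softmax; and
* a *modality* latent — an 8-vector from a variational encoder capturing
  contrast/intensity information.

A shallow three-layer segmentor reads the binary anatomy factors and
outputs background/LV/myocardium/RV probabilities.  A decoder fuses the
two latents with FiLM (feature-wise linear modulation) conditioning to
re-synthesize the image; the decoded image stacked with the interim
estimate feeds a refinement U-Net that produces the final reconstruction.

Training combines a segmentation loss (soft Dice + cross-entropy), the
closed-form KL divergence of the modality posterior, a modality
reconstruction loss (the decoded image must re-encode to the drawn
modality sample), and a perceptual reconstruction loss computed on a
frozen random convolutional feature pyramid plus a pixelwise L1 term.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn import Tensor


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and loss hyper-parameters."""

    n_factors: int = 8
    z_dim: int = 8
    base_width: int = 16
    unet_depth: int = 2
    n_classes: int = 4
    modality_sees_factors: bool = True
    loss_weights: tuple = (("seg", 10.0), ("kl", 0.01),
                           ("modality", 1.0), ("recon", 1.0))
    pixel_l1_weight: float = 1.0
    seed: int = 0

    def weights(self) -> dict:
        return dict(self.loss_weights)


@dataclass
class ModalityVector:
    """Gaussian posterior over the 8-dim modality latent."""

    mean: Tensor
    log_var: Tensor
    sample: Tensor


@dataclass
class ModelOutputs:
    seg_probs: Tensor        # (N, 4, H, W), per-pixel probabilities
    decoded: Tensor          # (N, 1, H, W)
    refined: Tensor          # (N, 1, H, W)
    factors_soft: Tensor     # (N, 8, H, W) in [0, 1]
    factors_bin: Tensor      # (N, 8, H, W) in {0, 1}
    modality: ModalityVector


@dataclass
class LossBundle:
    seg: float
    kl: float
    modality: float
    perceptual: float
    total: float

    def as_dict(self):
        return asdict(self)


class ConvBlock(nn.Module):
    def __init__(self, cin, cout, rng):
        self.net = nn.Sequential(
            nn.Conv2d(cin, cout, 3, rng=rng), nn.BatchNorm2d(cout), nn.LeakyReLU(),
            nn.Conv2d(cout, cout, 3, rng=rng), nn.BatchNorm2d(cout), nn.LeakyReLU())

    def forward(self, x):
        return self.net(x)


class UNet(nn.Module):
    """Encoder-decoder with skip connections; stride-2 down, nearest up."""

    def __init__(self, cin, cout, base=16, depth=2, rng=None):
        rng = rng or np.random.default_rng(0)
        self.depth = depth
        chans = [base * 2 ** i for i in range(depth + 1)]
        self.enc = [ConvBlock(cin if i == 0 else chans[i - 1], chans[i], rng)
                    for i in range(depth)]
        self.down = [nn.Conv2d(chans[i], chans[i], 3, stride=2, rng=rng)
                     for i in range(depth)]
        self.bottleneck = ConvBlock(chans[depth - 1], chans[depth], rng)
        self.up = [nn.Conv2d(chans[i + 1], chans[i], 3, rng=rng)
                   for i in reversed(range(depth))]
        self.dec = [ConvBlock(2 * chans[i], chans[i], rng)
                    for i in reversed(range(depth))]
        self.final = nn.Conv2d(chans[0], cout, 1, rng=rng)

    def forward(self, x):
        skips = []
        for enc, down in zip(self.enc, self.down):
            x = enc(x)
            skips.append(x)
            x = down(x)
        x = self.bottleneck(x)
        for up, dec, skip in zip(self.up, self.dec, reversed(skips)):
            x = up(nn.upsample_nearest(x))
            x = dec(nn.concat([x, skip], axis=1))
        return self.final(x)


class Segmentor(nn.Module):
    """Three conv layers with batch norm and LeakyReLU, then a softmax classifier."""

    def __init__(self, n_factors=8, n_classes=4, width=16, rng=None):
        rng = rng or np.random.default_rng(0)
        self.body = nn.Sequential(
            nn.Conv2d(n_factors, width, 3, rng=rng), nn.BatchNorm2d(width), nn.LeakyReLU(),
            nn.Conv2d(width, width, 3, rng=rng), nn.BatchNorm2d(width), nn.LeakyReLU(),
            nn.Conv2d(width, width, 3, rng=rng), nn.BatchNorm2d(width), nn.LeakyReLU())
        self.classifier = nn.Conv2d(width, n_classes, 1, rng=rng)

    def forward(self, factors):
        return nn.softmax(self.classifier(self.body(factors)), axis=1)


class ModalityEncoder(nn.Module):
    """Variational encoder producing the 8-dim modality posterior."""

    def __init__(self, cin, z_dim=8, base=16, rng=None):
        rng = rng or np.random.default_rng(0)
        self.z_dim = z_dim
        self.net = nn.Sequential(
            nn.Conv2d(cin, base, 3, stride=2, rng=rng), nn.LeakyReLU(),
            nn.Conv2d(base, 2 * base, 3, stride=2, rng=rng), nn.LeakyReLU(),
            nn.Conv2d(2 * base, 2 * base, 3, stride=2, rng=rng), nn.LeakyReLU())
        self.head = nn.Linear(2 * base, 2 * z_dim, rng=rng)

    def forward(self, x):
        h = self.net(x)
        pooled = nn.tmean(h, axis=(2, 3))          # (N, C)
        out = self.head(pooled)                    # (N, 2*z)
        mu = _take_half(out, self.z_dim, 0)
        lv = _take_half(out, self.z_dim, 1)
        return mu, lv


def _take_half(t: Tensor, z: int, which: int) -> Tensor:
    data = t.data[:, which * z:(which + 1) * z]

    def backward(g):
        full = np.zeros_like(t.data)
        full[:, which * z:(which + 1) * z] = g
        t._accum(full)

    return nn._node(data, (t,), backward)


class FiLMLayer(nn.Module):
    """Per-channel scale/shift of feature maps conditioned on the modality vector."""

    def __init__(self, z_dim, channels, rng=None):
        self.proj = nn.Linear(z_dim, 2 * channels, rng=rng)
        self.channels = channels

    def forward(self, x, z):
        gb = self.proj(z)                          # (N, 2C)
        gamma = _take_half(gb, self.channels, 0)
        beta = _take_half(gb, self.channels, 1)
        g4 = nn.reshape(gamma, (-1, self.channels, 1, 1))
        b4 = nn.reshape(beta, (-1, self.channels, 1, 1))
        return nn.add(nn.mul(x, nn.add(g4, nn.Tensor(np.float32(1.0)))), b4)


class FiLMDecoder(nn.Module):
    """Decodes binary anatomy factors into an image, modulated by z."""

    def __init__(self, n_factors=8, z_dim=8, base=32, rng=None):
        rng = rng or np.random.default_rng(0)
        self.convs = [nn.Conv2d(n_factors, base, 3, rng=rng),
                      nn.Conv2d(base, base, 3, rng=rng),
                      nn.Conv2d(base, base // 2, 3, rng=rng)]
        self.films = [FiLMLayer(z_dim, base, rng=rng),
                      FiLMLayer(z_dim, base, rng=rng),
                      FiLMLayer(z_dim, base // 2, rng=rng)]
        self.final = nn.Conv2d(base // 2, 1, 3, rng=rng)

    def forward(self, factors, z):
        x = factors
        for conv, film in zip(self.convs, self.films):
            x = nn.leaky_relu(film(conv(x), z))
        return self.final(x)


class PerceptualExtractor(nn.Module):
    """Frozen, seeded random convolutional feature pyramid (3 depths)."""

    def __init__(self, seed=0, base=8):
        rng = np.random.default_rng(seed)
        self.convs = [nn.Conv2d(1, base, 3, stride=2, rng=rng),
                      nn.Conv2d(base, 2 * base, 3, stride=2, rng=rng),
                      nn.Conv2d(2 * base, 4 * base, 3, stride=2, rng=rng)]
        for c in self.convs:
            c.weight.requires_grad = False
            c.bias.requires_grad = False

    def forward(self, x):
        feats = []
        for c in self.convs:
            x = nn.leaky_relu(c(x), 0.2)
            feats.append(x)
        return feats


class XSDNet(nn.Module):
    """The full disentangled reconstruction/segmentation network."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.anatomy = UNet(1, cfg.n_factors, base=cfg.base_width,
                            depth=cfg.unet_depth, rng=rng)
        self.segmentor = Segmentor(cfg.n_factors, cfg.n_classes,
                                   width=cfg.base_width, rng=rng)
        mod_in = 1 + (cfg.n_factors if cfg.modality_sees_factors else 0)
        self.modality_enc = ModalityEncoder(mod_in, cfg.z_dim,
                                            base=cfg.base_width, rng=rng)
        self.decoder = FiLMDecoder(cfg.n_factors, cfg.z_dim,
                                   base=2 * cfg.base_width, rng=rng)
        self.refiner = UNet(2, 1, base=cfg.base_width, depth=cfg.unet_depth,
                            rng=rng)
        self.perceptual = PerceptualExtractor(seed=cfg.seed + 101)
        self.sample_rng = np.random.default_rng(cfg.seed + 7)

    # -- pieces -----------------------------------------------------------
    def encode_anatomy(self, image: Tensor) -> Tensor:
        """Soft anatomy factors: 8 channel maps, channel-softmaxed to [0, 1]."""
        if not np.all(np.isfinite(image.data)):
            raise ValueError("non-finite input image")
        return nn.softmax(self.anatomy(image), axis=1)

    @staticmethod
    def binarize(factors: Tensor) -> Tensor:
        """Threshold at 0.5; gradient is straight-through during training."""
        return nn.binarize_ste(factors, 0.5)

    def encode_modality(self, image: Tensor, factors: Tensor) -> ModalityVector:
        inp = nn.concat([image, factors], axis=1) \
            if self.config.modality_sees_factors else image
        mu, lv = self.modality_enc(inp)
        if self.training:
            eps = self.sample_rng.standard_normal(mu.data.shape).astype(np.float32)
            sample = nn.add(mu, nn.mul(nn.exp(nn.mul(lv, nn._const(0.5))),
                                       nn.Tensor(eps)))
        else:
            sample = mu
        return ModalityVector(mean=mu, log_var=lv, sample=sample)

    # -- full forward ------------------------------------------------------
    def forward(self, image: np.ndarray | Tensor) -> ModelOutputs:
        x = image if isinstance(image, Tensor) else Tensor(image)
        if x.data.ndim == 2:
            x = nn.reshape(x, (1, 1) + x.data.shape)
        factors_soft = self.encode_anatomy(x)
        factors_bin = self.binarize(factors_soft)
        seg = self.segmentor(factors_bin)
        modality = self.encode_modality(x, factors_bin)
        decoded = self.decoder(factors_bin, modality.sample)
        # residual refinement: the network predicts a correction to the
        # interim estimate, so artifact removal starts from the identity
        refined = nn.add(self.refiner(nn.concat([decoded, x], axis=1)), x)
        return ModelOutputs(seg_probs=seg, decoded=decoded, refined=refined,
                            factors_soft=factors_soft, factors_bin=factors_bin,
                            modality=modality)

    # -- losses ------------------------------------------------------------
    def compute_losses(self, outputs: ModelOutputs, target_image: np.ndarray,
                       target_mask: np.ndarray,
                       weights: dict | None = None) -> tuple[Tensor, LossBundle]:
        """Weighted training objective; returns (total tensor, detached bundle)."""
        w = dict(self.config.weights())
        if weights:
            w.update(weights)
        n_cls = self.config.n_classes
        tgt_img = np.asarray(target_image, np.float32)
        if tgt_img.ndim == 3:
            tgt_img = tgt_img[:, None]
        onehot = _one_hot(np.asarray(target_mask), n_cls)

        seg = nn.add(soft_dice_loss(outputs.seg_probs, onehot),
                     cross_entropy(outputs.seg_probs, onehot))
        kl = kl_divergence(outputs.modality.mean, outputs.modality.log_var)

        # the decoded image must carry the modality information: re-encode
        re_mod = self.encode_modality(outputs.decoded, outputs.factors_bin)
        modality_loss = nn.tmean(nn.tabs(nn.add(
            re_mod.mean, nn.mul(outputs.modality.sample, nn._const(-1.0)))))

        tgt_t = Tensor(tgt_img)
        feats_p = self.perceptual(outputs.refined)
        feats_t = self.perceptual(tgt_t)
        perc = nn._const(0.0)
        for fp, ft in zip(feats_p, feats_t):
            d = nn.add(fp, nn.mul(ft, nn._const(-1.0)))
            perc = nn.add(perc, nn.tmean(nn.mul(d, d)))
        pix = nn.tmean(nn.tabs(nn.add(outputs.refined,
                                      nn.mul(tgt_t, nn._const(-1.0)))))
        perc = nn.add(perc, nn.mul(pix, nn._const(self.config.pixel_l1_weight)))

        total = nn.add(
            nn.add(nn.mul(seg, nn._const(w["seg"])), nn.mul(kl, nn._const(w["kl"]))),
            nn.add(nn.mul(modality_loss, nn._const(w["modality"])),
                   nn.mul(perc, nn._const(w["recon"]))))
        bundle = LossBundle(seg=float(seg.data), kl=float(kl.data),
                            modality=float(modality_loss.data),
                            perceptual=float(perc.data), total=float(total.data))
        return total, bundle

    # -- persistence ---------------------------------------------------
    def save(self, path: str):
        arrays = self.get_state()
        np.savez_compressed(path, config=json.dumps(asdict(self.config)),
                            **{f"arr_{i}": a for i, a in enumerate(arrays)})

    @classmethod
    def load(cls, path: str) -> "XSDNet":
        with np.load(path, allow_pickle=False) as z:
            cfg_dict = json.loads(str(z["config"]))
            cfg_dict["loss_weights"] = tuple(map(tuple, cfg_dict["loss_weights"]))
            model = cls(ModelConfig(**cfg_dict))
            arrays = [z[f"arr_{i}"] for i in range(len(z.files) - 1)]
        model.set_state(arrays)
        return model


# -- loss primitives -------------------------------------------------------

def _one_hot(mask: np.ndarray, n_classes: int) -> np.ndarray:
    m = np.asarray(mask)
    if m.ndim == 2:
        m = m[None]
    out = np.zeros((m.shape[0], n_classes) + m.shape[1:], np.float32)
    for c in range(n_classes):
        out[:, c] = (m == c)
    return out


def soft_dice_loss(probs: Tensor, onehot: np.ndarray, eps: float = 1e-6) -> Tensor:
    """1 - mean soft Dice over classes and batch."""
    t = Tensor(onehot)
    inter = nn.tsum(nn.mul(probs, t), axis=(2, 3))
    denom = nn.add(nn.tsum(probs, axis=(2, 3)), nn.tsum(t, axis=(2, 3)))
    dice = nn.mul(inter, nn.power(nn.add(denom, nn._const(eps)), -1.0))
    return nn.add(nn._const(1.0), nn.mul(nn.tmean(dice), nn._const(-2.0)))


def cross_entropy(probs: Tensor, onehot: np.ndarray) -> Tensor:
    t = Tensor(onehot)
    return nn.mul(nn.tmean(nn.tsum(nn.mul(t, nn.log(probs)), axis=1)),
                  nn._const(-1.0))


def kl_divergence(mu: Tensor, log_var: Tensor) -> Tensor:
    """KL(q || N(0, I)), closed form, averaged over the batch."""
    term = nn.add(nn.add(nn.mul(mu, mu), nn.exp(log_var)),
                  nn.add(nn.mul(log_var, nn._const(-1.0)), nn._const(-1.0)))
    return nn.mul(nn.tmean(nn.tsum(term, axis=1)), nn._const(0.5))


def normalize_magnitude(image: np.ndarray, percentile: float = 99.0) -> np.ndarray:
    """Magnitude image scaled into [0, 1] by its given percentile."""
    mag = np.abs(np.asarray(image))
    p = np.percentile(mag, percentile)
    return np.clip(mag / max(p, 1e-12), 0.0, 1.0).astype(np.float32)
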