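"""Conditional adversarial B-mode -> elastography translator.

The model is a pix2pix-style conditional GAN.  A U-Net generator maps a
1-channel B-mode image to a 3-channel pseudo-color elastogram in [-1, 1]
(Tanh output).  Two PatchGAN discriminators receive 4-channel composites
(B-mode + elastogram): a global one over the full image and a tumor
discriminator over the lesion crop, which sharpens elasticity realism where
it matters diagnostically.  The generator objective is

    L_G = lambda * gamma * L1(y_real, y_virtual)
          + CE(1, D(x, y_virtual)) + CE(1, D(x_tumor, y_virtual_tumor))

with lambda = 100 and gamma a per-pixel color-rebalancing weight: pixels are
quantized in Lab ab space and weighted by the inverse of the (alpha-smoothed)
empirical color frequency, gamma_p = (alpha * P~_p + (1 - alpha)/Q)^-1, so
the rare saturated reds and blues that carry the diagnostic signal are not
washed out by the dominant background colors.  Each discriminator is trained
with CE(1, D(real pair)) + CE(0, D(virtual pair)), entering the total with
weight 0.5.  Training alternates generator and discriminator Adam updates
(lr 2e-4, linear decay to zero from the configured epoch).
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from skimage.color import rgb2lab
from skimage.transform import resize as _sk_resize

from . import nn
from .nn import (Adam, BatchNorm2d, Conv2d, ConvTranspose2d, LeakyReLU, Param,
                 ReLU, Tanh, bce_logits, bce_logits_grad, sigmoid)

__all__ = [
    "GeneratorConfig", "DiscriminatorConfig", "TrainConfig", "RebalanceTable",
    "Checkpoint", "UNetGenerator", "PatchDiscriminator",
    "build_generator", "build_discriminator", "fit_rebalance_table",
    "generator_loss", "discriminator_losses", "train", "synthesize",
    "learning_rate_at", "tiny_generator_config", "tiny_discriminator_config",
    "tiny_train_config", "save_checkpoint", "load_checkpoint",
]


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class GeneratorConfig:
    """U-Net channel plan.  Defaults follow the standard image-translation
    layout: encoder input layer + 6 blocks with output channels
    64,128,256,512,512,512,512 (stride-2 4x4 convs; a 256 input reaches a
    2x2x512 bottleneck), decoder blocks with input channels
    512,1024,1024,1024,512,256,128 (skip concatenation doubles the width),
    final deconvolution + Tanh to 3 channels."""

    encoder_out_channels: tuple[int, ...] = (64, 128, 256, 512, 512, 512, 512)
    decoder_in_channels: tuple[int, ...] = (512, 1024, 1024, 1024, 512, 256, 128)
    kernel_size: int = 4
    input_channels: int = 1
    output_channels: int = 3

    def decoder_out_channels(self) -> tuple[int, ...]:
        """Per-block decoder output widths implied by the skip concatenations."""
        enc, dec = self.encoder_out_channels, self.decoder_in_channels
        m = len(enc)
        if len(dec) != m:
            raise ValueError("decoder_in_channels must match encoder length")
        if dec[0] != enc[-1]:
            raise ValueError("first decoder input must equal bottleneck width")
        outs = []
        for j in range(m - 1):
            out = dec[j + 1] - enc[m - 2 - j]
            if out <= 0:
                raise ValueError(
                    f"decoder block {j}: input {dec[j + 1]} incompatible with "
                    f"skip width {enc[m - 2 - j]}"
                )
            outs.append(out)
        return tuple(outs)


@dataclass(frozen=True)
class DiscriminatorConfig:
    """PatchGAN plan: 4-channel composite in, 1-channel patch logit map out.

    Default channels 64,128,256,512,512,1 with strides 2,2,2,1,1,1 give a
    receptive field of about 70 pixels per patch score."""

    input_channels: int = 4
    layer_out_channels: tuple[int, ...] = (64, 128, 256, 512, 512, 1)
    strides: tuple[int, ...] = (2, 2, 2, 1, 1, 1)
    kernel_size: int = 4
    leaky_slope: float = 0.2

    def __post_init__(self) -> None:
        if self.layer_out_channels[-1] != 1:
            raise ValueError("final discriminator layer must output 1 channel")
        if len(self.strides) != len(self.layer_out_channels):
            raise ValueError("strides and layer_out_channels must align")


def tiny_generator_config() -> GeneratorConfig:
    """4-downsampling, base-width-16 U-Net for 64x64 CPU experiments."""
    return GeneratorConfig(
        encoder_out_channels=(16, 32, 64, 128),
        decoder_in_channels=(128, 128, 64, 32),
    )


def tiny_discriminator_config() -> DiscriminatorConfig:
    return DiscriminatorConfig(
        layer_out_channels=(16, 32, 64, 1),
        strides=(2, 2, 2, 1),
    )


@dataclass(frozen=True)
class TrainConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    discriminator: DiscriminatorConfig = field(default_factory=DiscriminatorConfig)
    tumor_discriminator: DiscriminatorConfig = field(default_factory=DiscriminatorConfig)
    lambda_l1: float = 100.0
    discriminator_loss_weight: float = 0.5
    epochs: int = 200
    batch_size: int = 1
    learning_rate: float = 2e-4
    lr_decay_start_epoch: int = 100
    beta1: float = 0.5
    beta2: float = 0.999
    weight_init_std: float = 0.02
    adversarial: bool = True
    literal_printed_loss: bool = False  # variant: global fake term on the real target
    augment_flip: bool = True
    diffaug: bool = False
    diffaug_brightness: float = 0.2
    diffaug_translate_frac: float = 0.125
    tumor_crop_size: int = 128
    rebalance_alpha: float = 0.8
    rebalance_bin_width: float = 10.0
    rebalance_normalize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("rates and sizes must be positive")
        if not 1 <= self.lr_decay_start_epoch <= self.epochs:
            raise ValueError("lr_decay_start_epoch must lie within [1, epochs]")


def tiny_train_config(**overrides) -> TrainConfig:
    """Desk-scale training setup: 64x64 images, tiny nets, 30 epochs."""
    defaults = dict(
        generator=tiny_generator_config(),
        discriminator=tiny_discriminator_config(),
        tumor_discriminator=tiny_discriminator_config(),
        epochs=30,
        batch_size=8,
        tumor_crop_size=24,
        diffaug=False,
    )
    defaults.update(overrides)
    defaults.setdefault("lr_decay_start_epoch",
                        max(1, defaults["epochs"] // 2))
    return TrainConfig(**defaults)


def learning_rate_at(cfg: TrainConfig, epoch: int) -> float:
    """Learning rate for a 1-based epoch: constant, then linear decay to zero."""
    if epoch < cfg.lr_decay_start_epoch:
        return cfg.learning_rate
    span = cfg.epochs - cfg.lr_decay_start_epoch
    if span == 0:
        return 0.0 if epoch >= cfg.epochs else cfg.learning_rate
    return cfg.learning_rate * max(0.0, (cfg.epochs - epoch) / span)


# ---------------------------------------------------------------------------
# networks

class UNetGenerator:
    """Encoder-decoder with skip concatenations; blocks are ReLU -> (de)conv -> BN."""

    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator,
                 init_std: float = 0.02):
        self.cfg = cfg
        enc = cfg.encoder_out_channels
        dec_in = cfg.decoder_in_channels
        dec_out = cfg.decoder_out_channels()
        k = cfg.kernel_size
        m = len(enc)
        self.m = m

        self.enc_convs = [Conv2d(cfg.input_channels, enc[0], k, 2, 1, rng, init_std)]
        self.enc_bns: list[BatchNorm2d | None] = [None]
        self.enc_acts: list[ReLU | None] = [None]
        for i in range(1, m):
            self.enc_acts.append(ReLU())
            self.enc_convs.append(Conv2d(enc[i - 1], enc[i], k, 2, 1, rng, init_std))
            self.enc_bns.append(BatchNorm2d(enc[i], rng=rng, init_std=init_std))

        self.dec_acts = [ReLU() for _ in range(m - 1)]
        self.dec_deconvs = [
            ConvTranspose2d(dec_in[j], dec_out[j], k, 2, 1, rng, init_std)
            for j in range(m - 1)
        ]
        self.dec_bns = [BatchNorm2d(dec_out[j], rng=rng, init_std=init_std)
                        for j in range(m - 1)]
        self.out_act = ReLU()
        self.out_deconv = ConvTranspose2d(dec_in[m - 1], cfg.output_channels,
                                          k, 2, 1, rng, init_std)
        self.tanh = Tanh()
        self._dec_out = dec_out

    def params(self) -> list[Param]:
        ps: list[Param] = []
        for layer in (*self.enc_convs, *[b for b in self.enc_bns if b],
                      *self.dec_deconvs, *self.dec_bns, self.out_deconv):
            ps.extend(layer.params())
        return ps

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        m = self.m
        a = [self.enc_convs[0].forward(x, train)]
        for i in range(1, m):
            h = self.enc_acts[i].forward(a[-1], train)
            h = self.enc_convs[i].forward(h, train)
            a.append(self.enc_bns[i].forward(h, train))
        d = a[m - 1]
        for j in range(m - 1):
            if j > 0:
                d = np.concatenate([d, a[m - 1 - j]], axis=1)
            d = self.dec_acts[j].forward(d, train)
            d = self.dec_deconvs[j].forward(d, train)
            d = self.dec_bns[j].forward(d, train)
        d = np.concatenate([d, a[0]], axis=1)
        d = self.out_act.forward(d, train)
        d = self.out_deconv.forward(d, train)
        return self.tanh.forward(d, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        m = self.m
        dec_out = self._dec_out
        g = self.tanh.backward(dout)
        g = self.out_deconv.backward(g)
        g = self.out_act.backward(g)
        sg: list[np.ndarray | None] = [None] * (m - 1)  # grads into skip a[i]
        sg[0] = g[:, dec_out[m - 2]:]
        g = g[:, :dec_out[m - 2]]
        for j in range(m - 2, -1, -1):
            g = self.dec_bns[j].backward(g)
            g = self.dec_deconvs[j].backward(g)
            g = self.dec_acts[j].backward(g)
            if j > 0:
                sg[m - 1 - j] = g[:, dec_out[j - 1]:]
                g = g[:, :dec_out[j - 1]]
        # g is now the gradient w.r.t. the bottleneck activation a[m-1]
        for i in range(m - 1, 0, -1):
            g = self.enc_bns[i].backward(g)
            g = self.enc_convs[i].backward(g)
            g = self.enc_acts[i].backward(g)
            g = g + sg[i - 1]
        return self.enc_convs[0].backward(g)

    # -- checkpoint plumbing -------------------------------------------------
    def _stateful_layers(self):
        yield from self.enc_convs
        yield from (b for b in self.enc_bns if b is not None)
        yield from self.dec_deconvs
        yield from self.dec_bns
        yield self.out_deconv

    def state_arrays(self) -> dict[str, np.ndarray]:
        return _collect_state(self._stateful_layers())

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        _restore_state(self._stateful_layers(), state)


class PatchDiscriminator:
    """Stack of 4x4 convolutions producing a spatial real/fake logit map."""

    def __init__(self, cfg: DiscriminatorConfig, rng: np.random.Generator,
                 init_std: float = 0.02):
        self.cfg = cfg
        k = cfg.kernel_size
        chans = cfg.layer_out_channels
        self.convs, self.bns, self.acts = [], [], []
        cin = cfg.input_channels
        n = len(chans)
        for i, (cout, s) in enumerate(zip(chans, cfg.strides)):
            self.convs.append(Conv2d(cin, cout, k, s, 1, rng, init_std))
            last = i == n - 1
            self.bns.append(None if (i == 0 or last)
                            else BatchNorm2d(cout, rng=rng, init_std=init_std))
            self.acts.append(None if last else LeakyReLU(cfg.leaky_slope))
            cin = cout

    def params(self) -> list[Param]:
        ps: list[Param] = []
        for conv in self.convs:
            ps.extend(conv.params())
        for bn in self.bns:
            if bn is not None:
                ps.extend(bn.params())
        return ps

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = x
        for conv, bn, act in zip(self.convs, self.bns, self.acts):
            h = conv.forward(h, train)
            if bn is not None:
                h = bn.forward(h, train)
            if act is not None:
                h = act.forward(h, train)
        return h  # logits

    def backward(self, dout: np.ndarray, update_params: bool = True) -> np.ndarray:
        g = dout
        for conv, bn, act in zip(reversed(self.convs), reversed(self.bns),
                                 reversed(self.acts)):
            if act is not None:
                g = act.backward(g)
            if bn is not None:
                g = bn.backward(g, update_params)
            g = conv.backward(g, update_params)
        return g

    def _stateful_layers(self):
        yield from self.convs
        yield from (b for b in self.bns if b is not None)

    def state_arrays(self) -> dict[str, np.ndarray]:
        return _collect_state(self._stateful_layers())

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        _restore_state(self._stateful_layers(), state)


def _collect_state(layers) -> dict[str, np.ndarray]:
    state = {}
    for i, layer in enumerate(layers):
        for j, p in enumerate(layer.params()):
            state[f"l{i}_p{j}"] = p.data.copy()
        if isinstance(layer, BatchNorm2d):
            state[f"l{i}_rm"] = layer.running_mean.copy()
            state[f"l{i}_rv"] = layer.running_var.copy()
    return state


def _restore_state(layers, state: dict[str, np.ndarray]) -> None:
    for i, layer in enumerate(layers):
        for j, p in enumerate(layer.params()):
            p.data[...] = state[f"l{i}_p{j}"]
        if isinstance(layer, BatchNorm2d):
            layer.running_mean[...] = state[f"l{i}_rm"]
            layer.running_var[...] = state[f"l{i}_rv"]


def build_generator(cfg: GeneratorConfig, seed: int = 0,
                    init_std: float = 0.02) -> UNetGenerator:
    cfg.decoder_out_channels()  # validates consistency
    return UNetGenerator(cfg, np.random.default_rng(seed), init_std)


def build_discriminator(cfg: DiscriminatorConfig, seed: int = 0,
                        init_std: float = 0.02) -> PatchDiscriminator:
    return PatchDiscriminator(cfg, np.random.default_rng(seed), init_std)


# ---------------------------------------------------------------------------
# color rebalancing

@dataclass
class RebalanceTable:
    """Per-ab-bin inverse-frequency weights gamma_p = (alpha*P~ + (1-alpha)/Q)^-1.

    ``normalized`` rescales gamma so that its expectation under P~ equals 1,
    keeping lambda * gamma * L1 on the scale of a plain lambda * L1 loss;
    ``gamma_raw`` keeps the unnormalized values (magnitude ~ Q).
    """

    alpha: float
    bin_width: float
    q: int
    bins: np.ndarray            # (Q, 2) int bin coordinates (a, b)
    empirical_dist: np.ndarray  # (Q,) probabilities, sums to 1
    gamma_raw: np.ndarray       # (Q,)
    gamma: np.ndarray           # (Q,) possibly normalized
    normalized: bool
    _dense: np.ndarray | None = None
    _offset: tuple[int, int] = (0, 0)

    def _build_dense(self) -> None:
        # dense (a, b)-indexed lookup covering the whole ab gamut, so that
        # per-pixel weight lookup is a vectorized gather
        lo = np.floor(np.array([-128.0, -128.0]) / self.bin_width).astype(int)
        hi = np.ceil(np.array([128.0, 128.0]) / self.bin_width).astype(int)
        shape = (hi[0] - lo[0] + 1, hi[1] - lo[1] + 1)
        unseen_raw = 1.0 / ((1.0 - self.alpha) / self.q) if self.alpha < 1.0 \
            else float(self.gamma_raw.max())
        scale = self.gamma[0] / self.gamma_raw[0]
        dense = np.full(shape, unseen_raw * scale)
        dense[self.bins[:, 0] - lo[0], self.bins[:, 1] - lo[1]] = self.gamma
        self._dense = dense
        self._offset = (int(lo[0]), int(lo[1]))

    def weight_map(self, rgb01: np.ndarray) -> np.ndarray:
        """Per-pixel gamma for an (..., H, W, 3) RGB image in [0, 1]."""
        if self._dense is None:
            self._build_dense()
        lab = rgb2lab(np.clip(rgb01, 0.0, 1.0))
        ab = lab[..., 1:]
        idx = np.floor(ab / self.bin_width).astype(int)
        ia = np.clip(idx[..., 0] - self._offset[0], 0, self._dense.shape[0] - 1)
        ib = np.clip(idx[..., 1] - self._offset[1], 0, self._dense.shape[1] - 1)
        return self._dense[ia, ib]

    def state(self) -> dict:
        return {
            "alpha": self.alpha, "bin_width": self.bin_width, "q": self.q,
            "bins": self.bins.tolist(),
            "empirical_dist": self.empirical_dist.tolist(),
            "gamma_raw": self.gamma_raw.tolist(), "gamma": self.gamma.tolist(),
            "normalized": self.normalized,
        }

    @classmethod
    def from_state(cls, s: dict) -> "RebalanceTable":
        return cls(
            alpha=s["alpha"], bin_width=s["bin_width"], q=s["q"],
            bins=np.asarray(s["bins"], dtype=int),
            empirical_dist=np.asarray(s["empirical_dist"]),
            gamma_raw=np.asarray(s["gamma_raw"]),
            gamma=np.asarray(s["gamma"]),
            normalized=s["normalized"],
        )


def fit_rebalance_table(eus_images: Sequence[np.ndarray], alpha: float = 0.8,
                        bin_width: float = 10.0,
                        normalize: bool = True) -> RebalanceTable:
    """Estimate the ab-space color distribution of the training elastograms.

    ``eus_images`` are RGB arrays, either uint8 in [0, 255] or float in
    [0, 1].  Pixels are quantized on a ``bin_width`` grid in Lab ab
    coordinates; Q is the number of occupied bins.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if len(eus_images) == 0:
        raise ValueError("at least one training image is required")
    counts: dict[tuple[int, int], int] = {}
    for img in eus_images:
        arr = np.asarray(img)
        rgb01 = arr / 255.0 if arr.dtype != np.float64 or arr.max() > 1.0 else arr
        ab = rgb2lab(np.clip(rgb01, 0.0, 1.0))[..., 1:]
        idx = np.floor(ab / bin_width).astype(int).reshape(-1, 2)
        uniq, cnt = np.unique(idx, axis=0, return_counts=True)
        for key, n in zip(map(tuple, uniq), cnt):
            counts[key] = counts.get(key, 0) + int(n)
    bins = np.asarray(sorted(counts), dtype=int)
    cnt = np.asarray([counts[tuple(b)] for b in bins], dtype=np.float64)
    p_tilde = cnt / cnt.sum()
    q = len(bins)
    gamma_raw = 1.0 / (alpha * p_tilde + (1.0 - alpha) / q)
    gamma = gamma_raw / float((p_tilde * gamma_raw).sum()) if normalize \
        else gamma_raw.copy()
    return RebalanceTable(alpha=alpha, bin_width=bin_width, q=q, bins=bins,
                          empirical_dist=p_tilde, gamma_raw=gamma_raw,
                          gamma=gamma, normalized=normalize)


# ---------------------------------------------------------------------------
# losses (evaluative closed forms; the training loop uses the logit route)

_EPS = 1e-7


def _ce_prob(label: float, probs: np.ndarray) -> float:
    """Mean cross-entropy of a constant label against probabilities in (0,1)."""
    p = np.clip(np.asarray(probs, dtype=np.float64), _EPS, 1.0 - _EPS)
    return float(np.mean(-(label * np.log(p) + (1.0 - label) * np.log(1.0 - p))))


def _weighted_l1(y_virtual: np.ndarray, y_real: np.ndarray,
                 table: RebalanceTable | None) -> float:
    if table is None:
        w = np.ones(y_real.shape[:-1] if y_real.ndim == 3 else y_real.shape)
    else:
        w = table.weight_map((y_real + 1.0) / 2.0 if y_real.min() < 0 else y_real)
    diff = np.abs(y_virtual - y_real)
    if diff.ndim == 3:
        w = w[..., None]
    return float(np.mean(w * diff))


def _crop_pair(x: np.ndarray, y: np.ndarray, roi) -> tuple[np.ndarray, np.ndarray]:
    r, c, h, w = roi
    if r < 0 or c < 0 or r + h > x.shape[0] or c + w > x.shape[1]:
        raise ValueError(f"roi {roi} outside image of shape {x.shape[:2]}")
    return x[r:r + h, c:c + w], y[r:r + h, c:c + w]


def generator_loss(x: np.ndarray, y_virtual: np.ndarray, y_real: np.ndarray,
                   roi, table: RebalanceTable | None,
                   d_global: Callable[[np.ndarray, np.ndarray], np.ndarray],
                   d_tumor: Callable[[np.ndarray, np.ndarray], np.ndarray],
                   lambda_l1: float = 100.0) -> dict[str, float]:
    """Generator objective: rebalanced L1 plus both adversarial fooling terms.

    ``d_global`` and ``d_tumor`` map (bus, eus) to real-probability maps.
    Returns the total and its components.
    """
    l1 = _weighted_l1(y_virtual, y_real, table)
    x_t, yv_t = _crop_pair(x, y_virtual, roi)
    adv_global = _ce_prob(1.0, d_global(x, y_virtual))
    adv_tumor = _ce_prob(1.0, d_tumor(x_t, yv_t))
    total = lambda_l1 * l1 + adv_global + adv_tumor
    return {"total": total, "l1": l1, "weighted_l1": lambda_l1 * l1,
            "adv_global": adv_global, "adv_tumor": adv_tumor}


def discriminator_losses(x: np.ndarray, y_real: np.ndarray, y_virtual: np.ndarray,
                         roi,
                         d_global: Callable[[np.ndarray, np.ndarray], np.ndarray],
                         d_tumor: Callable[[np.ndarray, np.ndarray], np.ndarray],
                         literal_printed_loss: bool = False) -> dict[str, float]:
    """Both discriminators' objectives (each enters the total with weight 0.5).

    ``literal_printed_loss`` evaluates the global discriminator's fake term on
    the real pair instead of the virtual pair; that variant makes the global
    discriminator independent of the generator and is kept for comparison
    experiments only.
    """
    fake_global = y_real if literal_printed_loss else y_virtual
    d_g = _ce_prob(1.0, d_global(x, y_real)) + _ce_prob(0.0, d_global(x, fake_global))
    x_t, yr_t = _crop_pair(x, y_real, roi)
    _, yv_t = _crop_pair(x, y_virtual, roi)
    d_t = _ce_prob(1.0, d_tumor(x_t, yr_t)) + _ce_prob(0.0, d_tumor(x_t, yv_t))
    return {"d_global": d_g, "d_tumor": d_t, "weighted_total": 0.5 * d_g + 0.5 * d_t}


# ---------------------------------------------------------------------------
# training

class _TumorCrop:
    """Differentiable per-sample ROI crop + nearest-neighbor resize."""

    def __init__(self, size: int):
        self.size = size

    def forward(self, batch: np.ndarray, rois: Sequence[tuple[int, int, int, int]]
                ) -> np.ndarray:
        n, c, _, _ = batch.shape
        s = self.size
        out = np.empty((n, c, s, s))
        self._idx = []
        self._in_shape = batch.shape
        for i, (r, cc, h, w) in enumerate(rois):
            ri = r + (np.arange(s) * h // s)
            ci = cc + (np.arange(s) * w // s)
            self._idx.append((ri, ci))
            out[i] = batch[i][:, ri[:, None], ci[None, :]]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._in_shape)
        for i, (ri, ci) in enumerate(self._idx):
            np.add.at(dx[i], (slice(None), ri[:, None], ci[None, :]), dout[i])
        return dx


def _make_diffaug(rng: np.random.Generator, cfg: TrainConfig, hw: tuple[int, int]):
    """One sampled differentiable-augmentation policy (brightness + translation)."""
    db = rng.uniform(-cfg.diffaug_brightness, cfg.diffaug_brightness)
    max_t = max(1, int(cfg.diffaug_translate_frac * min(hw)))
    tr = rng.integers(-max_t, max_t + 1, size=2)

    def apply(z: np.ndarray) -> np.ndarray:
        return np.roll(z + db, (int(tr[0]), int(tr[1])), axis=(2, 3))

    def grad(g: np.ndarray) -> np.ndarray:
        return np.roll(g, (-int(tr[0]), -int(tr[1])), axis=(2, 3))

    return apply, grad


def _cases_to_arrays(dataset) -> tuple[np.ndarray, np.ndarray, list]:
    """Normalize a list of CaseRecord-likes to model-space arrays."""
    xs, ys, rois = [], [], []
    for case in dataset:
        xs.append(case.bus.astype(np.float64) / 127.5 - 1.0)
        ys.append(case.eus.astype(np.float64).transpose(2, 0, 1) / 127.5 - 1.0)
        rois.append(tuple(case.roi))
    return np.stack(xs)[:, None], np.stack(ys), rois


@dataclass
class Checkpoint:
    generator: UNetGenerator
    d_global: PatchDiscriminator | None
    d_tumor: PatchDiscriminator | None
    table: RebalanceTable
    config: TrainConfig
    epoch: int
    optimizer_state: dict


def train(dataset, cfg: TrainConfig, log_path: str | Path | None = None,
          ) -> tuple[Checkpoint, pd.DataFrame]:
    """Alternating adversarial training on registered (BUS, EUS, ROI) cases.

    The rebalance table is fitted once on the training elastograms before the
    loop.  Augmentation (horizontal flip) is applied identically to each
    pair; the optional differentiable-augmentation policy perturbs both
    discriminator inputs.  Deterministic for a fixed config seed.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(cfg.seed)
    x_all, y_all, rois_all = _cases_to_arrays(dataset)
    n, _, H, W = x_all.shape

    table = fit_rebalance_table(
        [case.eus for case in dataset], alpha=cfg.rebalance_alpha,
        bin_width=cfg.rebalance_bin_width, normalize=cfg.rebalance_normalize)

    gen = UNetGenerator(cfg.generator, rng, cfg.weight_init_std)
    opt_g = Adam(gen.params(), cfg.learning_rate, (cfg.beta1, cfg.beta2))
    if cfg.adversarial:
        d_global = PatchDiscriminator(cfg.discriminator, rng, cfg.weight_init_std)
        d_tumor = PatchDiscriminator(cfg.tumor_discriminator, rng, cfg.weight_init_std)
        opt_dg = Adam(d_global.params(), cfg.learning_rate, (cfg.beta1, cfg.beta2))
        opt_dt = Adam(d_tumor.params(), cfg.learning_rate, (cfg.beta1, cfg.beta2))
    else:
        d_global = d_tumor = None
    crop_op_g = _TumorCrop(cfg.tumor_crop_size)
    crop_op_d = _TumorCrop(cfg.tumor_crop_size)

    log_rows = []
    for epoch in range(1, cfg.epochs + 1):
        lr = learning_rate_at(cfg, epoch)
        opt_g.lr = lr
        if cfg.adversarial:
            opt_dg.lr = opt_dt.lr = lr
        order = rng.permutation(n)
        sums = {"l1": 0.0, "adv_g": 0.0, "d_global": 0.0, "d_tumor": 0.0}
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            x = x_all[idx].copy()
            y = y_all[idx].copy()
            rois = [rois_all[i] for i in idx]
            if cfg.augment_flip and rng.random() < 0.5:
                x = x[:, :, :, ::-1].copy()
                y = y[:, :, :, ::-1].copy()
                rois = [(r, W - c - w, h, w) for (r, c, h, w) in rois]

            wmap = table.weight_map((y.transpose(0, 2, 3, 1) + 1.0) / 2.0)
            wmap = wmap[:, None]  # (B,1,H,W), broadcast over channels

            # ---- generator update -----------------------------------------
            yv = gen.forward(x, train=True)
            diff = yv - y
            l1 = float(np.mean(wmap * np.abs(diff)))
            dyv = cfg.lambda_l1 * wmap * np.sign(diff) / diff.size
            adv_g_val = 0.0
            if cfg.adversarial:
                aug, aug_grad = (_make_diffaug(rng, cfg, (H, W)) if cfg.diffaug
                                 else (lambda z: z, lambda g: g))
                comp = aug(np.concatenate([x, yv], axis=1))
                z = d_global.forward(comp, train=True)
                adv_g_val += bce_logits(1.0, z)
                dcomp = d_global.backward(bce_logits_grad(1.0, z),
                                          update_params=False)
                dyv += aug_grad(dcomp)[:, 1:4]
                crop = crop_op_g.forward(np.concatenate([x, yv], axis=1), rois)
                zt = d_tumor.forward(crop, train=True)
                adv_g_val += bce_logits(1.0, zt)
                dcrop = d_tumor.backward(bce_logits_grad(1.0, zt),
                                         update_params=False)
                dyv += crop_op_g.backward(dcrop)[:, 1:4]
            opt_g.zero_grad()
            gen.backward(dyv)
            opt_g.step()

            # ---- discriminator updates ------------------------------------
            dg_val = dt_val = 0.0
            if cfg.adversarial:
                aug, _ = (_make_diffaug(rng, cfg, (H, W)) if cfg.diffaug
                          else (lambda z: z, lambda g: g))
                wD = cfg.discriminator_loss_weight
                comp_real = aug(np.concatenate([x, y], axis=1))
                comp_fake_src = y if cfg.literal_printed_loss else yv
                comp_fake = aug(np.concatenate([x, comp_fake_src], axis=1))
                opt_dg.zero_grad()
                z = d_global.forward(comp_real, train=True)
                dg_val += bce_logits(1.0, z)
                d_global.backward(wD * bce_logits_grad(1.0, z))
                z = d_global.forward(comp_fake, train=True)
                dg_val += bce_logits(0.0, z)
                d_global.backward(wD * bce_logits_grad(0.0, z))
                opt_dg.step()

                opt_dt.zero_grad()
                crop_real = crop_op_d.forward(np.concatenate([x, y], axis=1), rois)
                zt = d_tumor.forward(crop_real, train=True)
                dt_val += bce_logits(1.0, zt)
                d_tumor.backward(wD * bce_logits_grad(1.0, zt))
                crop_fake = crop_op_d.forward(np.concatenate([x, yv], axis=1), rois)
                zt = d_tumor.forward(crop_fake, train=True)
                dt_val += bce_logits(0.0, zt)
                d_tumor.backward(wD * bce_logits_grad(0.0, zt))
                opt_dt.step()

            if not np.isfinite(l1) or not np.isfinite(adv_g_val):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} (l1={l1}, adv={adv_g_val})"
                )
            sums["l1"] += l1
            sums["adv_g"] += adv_g_val
            sums["d_global"] += dg_val
            sums["d_tumor"] += dt_val
            n_batches += 1

        log_rows.append({
            "epoch": epoch, "lr": lr,
            **{k: v / n_batches for k, v in sums.items()},
        })

    log = pd.DataFrame(log_rows)
    if log_path is not None:
        log.to_csv(log_path, index=False)
    ckpt = Checkpoint(
        generator=gen, d_global=d_global, d_tumor=d_tumor, table=table,
        config=cfg, epoch=cfg.epochs,
        optimizer_state={"g_t": opt_g.t},
    )
    return ckpt, log


# ---------------------------------------------------------------------------
# inference and checkpoint I/O

def synthesize(bus: np.ndarray, ckpt: Checkpoint) -> np.ndarray:
    """Map an 8-bit grayscale B-mode image to an 8-bit RGB virtual elastogram.

    The input is resized to the trained resolution if needed, pushed through
    the generator in inference mode (running batch statistics), and the
    output resized back, so output dimensions equal input dimensions.
    """
    bus = np.asarray(bus)
    if bus.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    h0, w0 = bus.shape
    gen = ckpt.generator
    n_down = gen.m
    trained = 2 ** n_down  # minimal divisor; use the input size if compatible
    h = max(trained, (h0 // trained) * trained)
    w = max(trained, (w0 // trained) * trained)
    x = bus.astype(np.float64) / 127.5 - 1.0
    if (h, w) != (h0, w0):
        x = _sk_resize(x, (h, w), order=1, mode="reflect", anti_aliasing=False)
    out = gen.forward(x[None, None], train=False)[0]
    rgb = np.clip((out.transpose(1, 2, 0) + 1.0) * 127.5, 0, 255)
    if (h, w) != (h0, w0):
        rgb = _sk_resize(rgb, (h0, w0), order=1, mode="reflect",
                         anti_aliasing=False)
    return np.rint(rgb).astype(np.uint8)


def save_checkpoint(ckpt: Checkpoint, path: str | Path) -> None:
    """Single-file archive: network states as npz plus a JSON config snapshot."""
    arrays = {f"gen_{k}": v for k, v in ckpt.generator.state_arrays().items()}
    if ckpt.d_global is not None:
        arrays.update({f"dg_{k}": v for k, v in ckpt.d_global.state_arrays().items()})
    if ckpt.d_tumor is not None:
        arrays.update({f"dt_{k}": v for k, v in ckpt.d_tumor.state_arrays().items()})
    meta = {
        "config": _config_to_dict(ckpt.config),
        "epoch": ckpt.epoch,
        "table": ckpt.table.state(),
        "optimizer_state": ckpt.optimizer_state,
    }
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path: str | Path) -> Checkpoint:
    try:
        data = np.load(path, allow_pickle=False)
        meta = json.loads(bytes(data["meta_json"]).decode())
    except Exception as exc:  # noqa: BLE001 - surfaced as a clear error
        raise ValueError(f"corrupt or unreadable checkpoint {path}: {exc}") from exc
    cfg = _config_from_dict(meta["config"])
    rng = np.random.default_rng(0)
    gen = UNetGenerator(cfg.generator, rng, cfg.weight_init_std)
    gen.load_state({k[4:]: data[k] for k in data.files if k.startswith("gen_")})
    d_global = d_tumor = None
    if any(k.startswith("dg_") for k in data.files):
        d_global = PatchDiscriminator(cfg.discriminator, rng, cfg.weight_init_std)
        d_global.load_state({k[3:]: data[k] for k in data.files if k.startswith("dg_")})
    if any(k.startswith("dt_") for k in data.files):
        d_tumor = PatchDiscriminator(cfg.tumor_discriminator, rng, cfg.weight_init_std)
        d_tumor.load_state({k[3:]: data[k] for k in data.files if k.startswith("dt_")})
    return Checkpoint(
        generator=gen, d_global=d_global, d_tumor=d_tumor,
        table=RebalanceTable.from_state(meta["table"]),
        config=cfg, epoch=meta["epoch"],
        optimizer_state=meta["optimizer_state"],
    )


def _config_to_dict(cfg: TrainConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def _config_from_dict(d: dict) -> TrainConfig:
    d = dict(d)
    for key, cls in (("generator", GeneratorConfig),
                     ("discriminator", DiscriminatorConfig),
                     ("tumor_discriminator", DiscriminatorConfig)):
        sub = {k: tuple(v) if isinstance(v, list) else v for k, v in d[key].items()}
        d[key] = cls(**sub)
    return TrainConfig(**d)
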