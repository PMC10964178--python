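"""Discriminators and the five-term training objective.

The full objective is

    L = L_adv(G_OH, D_H) + L_adv(G_HO, D_O)
        + alpha * L_cycle + beta * L_embedding
        + gamma * L_SC + iota * L_PA

with least-squares adversarial terms (the CycleGAN convention), L1 cycle
consistency, an L1 bottleneck-embedding consistency term, pixel-wise
cross-entropy over the three wall layers for the structural constraint, and
binary cross-entropy on the normal/pathological score for pathology
awareness.  Default weights are alpha=1, beta=0.2, gamma=5, iota=5.

The discriminator is a 70x70-receptive-field patch discriminator (PatchGAN):
it scores overlapping image patches with a fully convolutional stack, and
its receptive field can be computed analytically from the layer geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "LossWeights", "LossBreakdown", "Discriminator", "discriminator_receptive_field",
    "adversarial_loss", "adversarial_loss_from_scores", "cycle_loss",
    "embedding_loss", "sc_loss", "pa_loss", "total_loss",
    "LOSS_CSV_COLUMNS",
]

LOSS_CSV_COLUMNS = ("step", "adv_H", "adv_O", "cycle", "embedding", "sc", "pa", "total")

_EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    """Weights of the cycle, embedding, structural and pathology terms."""

    alpha: float = 1.0
    beta: float = 0.2
    gamma: float = 5.0
    iota: float = 5.0

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma, self.iota) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass(frozen=True)
class LossBreakdown:
    """The five loss terms and their weighted total (exact identity)."""

    adv_H: float
    adv_O: float
    cycle: float
    embedding: float
    sc: float
    pa: float
    total: float

    def verify(self, weights: LossWeights, tol: float = 0.0) -> bool:
        expected = (self.adv_H + self.adv_O + weights.alpha * self.cycle
                    + weights.beta * self.embedding + weights.gamma * self.sc
                    + weights.iota * self.pa)
        return abs(expected - self.total) <= tol


# -- discriminator ----------------------------------------------------------

_PATCHGAN_LAYERS = ((4, 2), (4, 2), (4, 2), (4, 1), (4, 1))  # (kernel, stride)


def discriminator_receptive_field(layers=_PATCHGAN_LAYERS) -> int:
    """Receptive field of a conv stack: 1 + sum (k_i - 1) * prod_{j<i} s_j."""
    rf, jump = 1, 1
    for k, s in layers:
        rf += (k - 1) * jump
        jump *= s
    return rf


class Discriminator(nn.Module):
    """PatchGAN: 3 stride-2 conv blocks + 2 stride-1 layers -> score map.

    The layer stack gives a 70-pixel receptive field per output score, so
    each score judges one 70x70 patch of the input.
    """

    def __init__(self, in_channels: int, rng: np.random.Generator,
                 base_width: int = 8):
        w = base_width
        ks = _PATCHGAN_LAYERS
        chans = [in_channels, w, 2 * w, 4 * w, 8 * w, 1]
        self.convs = [nn.Conv2d(chans[i], chans[i + 1], ks[i][0], rng,
                                stride=ks[i][1], padding=1)
                      for i in range(5)]
        self.norms = [None, nn.InstanceNorm2d(2 * w), nn.InstanceNorm2d(4 * w),
                      nn.InstanceNorm2d(8 * w), None]

    @property
    def receptive_field(self) -> int:
        return discriminator_receptive_field()

    def forward(self, x: Tensor) -> Tensor:
        for i, conv in enumerate(self.convs):
            x = conv(x)
            if self.norms[i] is not None:
                x = self.norms[i](x)
            if i < 4:
                x = x.leaky_relu(0.2)
        return x


# -- loss terms -------------------------------------------------------------

def adversarial_loss_from_scores(d_real: Tensor, d_fake: Tensor) -> tuple[Tensor, Tensor]:
    """Least-squares GAN terms from discriminator score maps.

    Returns ``(generator_term, discriminator_term)``:
    generator term  E[(D(fake) - 1)^2];
    discriminator term E[(D(real) - 1)^2] + E[D(fake)^2].
    For the discriminator update the *fake image* must be detached before
    scoring (as :func:`adversarial_loss` and the trainer do), so generator
    parameters receive no gradient from the discriminator term.
    """
    gen = ((d_fake - 1.0) ** 2).mean()
    disc = ((d_real - 1.0) ** 2).mean() + (d_fake ** 2).mean()
    return gen, disc


def adversarial_loss(discriminator, real_batch, fake_batch) -> tuple[Tensor, Tensor]:
    """Least-squares adversarial terms for a real/fake batch pair."""
    real = real_batch if isinstance(real_batch, Tensor) else Tensor(real_batch)
    fake = fake_batch if isinstance(fake_batch, Tensor) else Tensor(fake_batch)
    if real.shape[0] == 0 or fake.shape[0] == 0:
        raise ValueError("adversarial loss needs non-empty batches")
    gen, _ = adversarial_loss_from_scores(Tensor(0.0), discriminator(fake))
    # discriminator sees the fake without generator gradients
    _, disc = adversarial_loss_from_scores(discriminator(real),
                                           discriminator(fake.detach()))
    return gen, disc


def _call(g, x: Tensor) -> Tensor:
    """Apply a generator; unwrap structured outputs to the translated image."""
    out = g(x)
    return out.translated if hasattr(out, "translated") else out


def cycle_loss(g_ab, g_ba, batch_a, batch_b) -> Tensor:
    """Mean L1 reconstruction error of both cycles A->B->A and B->A->B."""
    a = batch_a if isinstance(batch_a, Tensor) else Tensor(batch_a)
    b = batch_b if isinstance(batch_b, Tensor) else Tensor(batch_b)
    rec_a = _call(g_ba, _call(g_ab, a))
    rec_b = _call(g_ab, _call(g_ba, b))
    return (rec_a - a).abs().mean() + (rec_b - b).abs().mean()


def embedding_loss(g_ab, g_ba, batch_a, batch_b) -> Tensor:
    """Bottleneck-embedding consistency over both cycles.

    Mean L1 distance between the bottleneck embedding of an input and the
    bottleneck embedding of its cycle reconstruction, summed over both
    directions.  ``g_ab``/``g_ba`` must expose ``embed(x)`` returning the
    bottleneck features.
    """
    a = batch_a if isinstance(batch_a, Tensor) else Tensor(batch_a)
    b = batch_b if isinstance(batch_b, Tensor) else Tensor(batch_b)
    for g in (g_ab, g_ba):
        if not hasattr(g, "embed"):
            raise AttributeError("generators must expose embed() for embedding loss")
    rec_a = _call(g_ba, _call(g_ab, a))
    rec_b = _call(g_ab, _call(g_ba, b))
    return ((g_ab.embed(a) - g_ab.embed(rec_a)).abs().mean()
            + (g_ba.embed(b) - g_ba.embed(rec_b)).abs().mean())


def sc_loss(seg_pred, labels: np.ndarray, valid: np.ndarray) -> Tensor:
    """Structural-constraint loss: masked pixel-wise cross-entropy.

    ``seg_pred`` is an (..., H, W, K) per-pixel class-probability map,
    ``labels`` an integer layer mask and ``valid`` a boolean mask of the
    pixels that carry supervision (background and unlabeled pixels are
    excluded).  Returns the mean of -log p(true class) over valid pixels,
    or exact zero when no pixel is valid.
    """
    pred = seg_pred if isinstance(seg_pred, Tensor) else Tensor(seg_pred)
    labels = np.asarray(labels)
    valid = np.asarray(valid, dtype=bool)
    if valid.shape != labels.shape:
        raise ValueError("labels and valid mask must have the same shape")
    if not valid.any():
        return Tensor(0.0)
    k = pred.shape[-1]
    lab = labels[valid]
    if lab.min() < 0 or lab.max() >= k:
        raise ValueError(f"labels on valid pixels must lie in [0, {k})")
    onehot = np.zeros(valid.shape + (k,), dtype=np.float32)
    flat_idx = np.nonzero(valid)
    onehot[flat_idx + (lab,)] = 1.0
    p_true = (pred * onehot).sum(axis=-1)
    logp = (p_true + (1.0 - valid.astype(np.float32))).clip(_EPS, 1.0).log()
    return -(logp * valid.astype(np.float32)).sum() / float(valid.sum())


def pa_loss(p, y) -> Tensor:
    """Pathology-awareness loss: binary cross-entropy, clamped at 1e-7."""
    pt = p if isinstance(p, Tensor) else Tensor(p)
    yv = np.asarray(y, dtype=np.float32)
    pc = pt.clip(_EPS, 1.0 - _EPS)
    return -(yv * pc.log() + (1.0 - yv) * (1.0 - pc).log()).mean()


def total_loss(adv_H: float, adv_O: float, cycle: float, embedding: float,
               sc: float, pa: float, weights: LossWeights) -> LossBreakdown:
    """Weighted five-term total; rejects non-finite components by name."""
    parts = {"adv_H": adv_H, "adv_O": adv_O, "cycle": cycle,
             "embedding": embedding, "sc": sc, "pa": pa}
    for name, val in parts.items():
        if not math.isfinite(float(val)):
            raise ValueError(f"loss component '{name}' is not finite: {val}")
    total = (adv_H + adv_O + weights.alpha * cycle + weights.beta * embedding
             + weights.gamma * sc + weights.iota * pa)
    return LossBreakdown(adv_H=float(adv_H), adv_O=float(adv_O),
                         cycle=float(cycle), embedding=float(embedding),
                         sc=float(sc), pa=float(pa), total=float(total))
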