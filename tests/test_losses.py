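"""Closed forms and oracles for the five-term objective and PatchGAN."""

import math

import numpy as np
import pytest

from octstain.losses import (Discriminator, LossWeights,
                             adversarial_loss, adversarial_loss_from_scores,
                             cycle_loss, discriminator_receptive_field,
                             embedding_loss, pa_loss, sc_loss, total_loss)
from octstain.nn import Tensor

RNG = np.random.default_rng(7)


class _Identity:
    def __call__(self, x):
        return x

    def embed(self, x):
        return x


class _Offset:
    """Adds a constant; cycles through two of these offset by +0.1 total."""

    def __init__(self, c):
        self.c = c

    def __call__(self, x):
        return x + self.c

    def embed(self, x):
        return x + 2.0 * self.c


# -- adversarial ------------------------------------------------------------

def test_adversarial_perfect_discriminator():
    d_real = Tensor(np.ones((3, 1, 2, 2), dtype=np.float32))
    d_fake = Tensor(np.zeros((3, 1, 2, 2), dtype=np.float32))
    gen, disc = adversarial_loss_from_scores(d_real, d_fake)
    assert disc.item() == pytest.approx(0.0)
    assert gen.item() == pytest.approx(1.0)


def test_adversarial_indifferent_discriminator():
    half = Tensor(np.full((2, 1, 2, 2), 0.5, dtype=np.float32))
    _, disc = adversarial_loss_from_scores(half, half)
    assert disc.item() == pytest.approx(0.5)  # 0.25 + 0.25


def test_adversarial_matches_hand_computed_means():
    for trial in range(5):
        rng = np.random.default_rng(trial)
        r = rng.random((3, 1, 4, 4)).astype(np.float32)
        f = rng.random((3, 1, 4, 4)).astype(np.float32)
        gen, disc = adversarial_loss_from_scores(Tensor(r), Tensor(f))
        assert gen.item() == pytest.approx(((f - 1) ** 2).mean(), abs=1e-7)
        assert disc.item() == pytest.approx(
            ((r - 1) ** 2).mean() + (f ** 2).mean(), abs=1e-7)


def test_adversarial_loss_runs_a_discriminator():
    d = Discriminator(1, np.random.default_rng(0), base_width=4)
    real = RNG.random((2, 1, 64, 64)).astype(np.float32)
    fake = RNG.random((2, 1, 64, 64)).astype(np.float32)
    gen, disc = adversarial_loss(d, real, fake)
    assert np.isfinite(gen.item()) and np.isfinite(disc.item())
    with pytest.raises(ValueError):
        adversarial_loss(d, real[:0], fake)


# -- cycle / embedding ------------------------------------------------------

def test_cycle_identity_generators_give_zero():
    x = Tensor(RNG.random((2, 1, 4, 4)).astype(np.float32))
    assert cycle_loss(_Identity(), _Identity(), x, x).item() == pytest.approx(0.0)


def test_cycle_constant_offset():
    x = Tensor(np.zeros((1, 1, 4, 4), dtype=np.float32))
    # each direction's cycle output = input + 0.1 -> L1 = 0.1 per direction
    val = cycle_loss(_Offset(0.05), _Offset(0.05), x, x).item()
    assert val == pytest.approx(0.2, abs=1e-6)


def test_cycle_matches_direct_l1():
    a = RNG.random((2, 1, 3, 3)).astype(np.float32)
    b = RNG.random((2, 1, 3, 3)).astype(np.float32)
    g1, g2 = _Offset(0.3), _Offset(-0.1)
    got = cycle_loss(g1, g2, Tensor(a), Tensor(b)).item()
    want = (np.abs((a + 0.2) - a).mean() + np.abs((b + 0.2) - b).mean())
    assert got == pytest.approx(want, abs=1e-6)


def test_embedding_identity_and_offset():
    x = Tensor(RNG.random((1, 1, 4, 4)).astype(np.float32))
    assert embedding_loss(_Identity(), _Identity(), x, x).item() == pytest.approx(0.0)
    # cycle shifts input by 0.2, embed is linear-plus-constant -> |delta|=0.2
    val = embedding_loss(_Offset(0.1), _Offset(0.1), x, x).item()
    assert val == pytest.approx(0.4, abs=1e-6)


def test_embedding_requires_embed_method():
    with pytest.raises(AttributeError):
        embedding_loss(lambda x: x, lambda x: x,
                       Tensor(np.zeros((1, 1, 2, 2), dtype=np.float32)),
                       Tensor(np.zeros((1, 1, 2, 2), dtype=np.float32)))


# -- structural constraint --------------------------------------------------

def test_sc_perfect_prediction_is_zero():
    labels = RNG.integers(0, 3, (8, 8))
    pred = np.eye(3, dtype=np.float32)[labels]
    valid = np.ones((8, 8), dtype=bool)
    assert sc_loss(pred, labels, valid).item() == pytest.approx(0.0, abs=1e-5)


def test_sc_uniform_prediction_is_ln3():
    pred = np.full((8, 8, 3), 1.0 / 3.0, dtype=np.float32)
    labels = RNG.integers(0, 3, (8, 8))
    valid = np.ones((8, 8), dtype=bool)
    assert sc_loss(pred, labels, valid).item() == pytest.approx(math.log(3), abs=1e-6)


def test_sc_matches_per_pixel_hand_summation():
    rng = np.random.default_rng(5)
    logits = rng.random((8, 8, 3)).astype(np.float32) + 0.1
    pred = logits / logits.sum(axis=-1, keepdims=True)
    labels = rng.integers(0, 3, (8, 8))
    valid = rng.random((8, 8)) < 0.7
    got = sc_loss(pred, labels, valid).item()
    acc, n = 0.0, 0
    for y in range(8):
        for x in range(8):
            if valid[y, x]:
                acc -= math.log(pred[y, x, labels[y, x]])
                n += 1
    assert got == pytest.approx(acc / n, abs=1e-6)


def test_sc_empty_valid_mask_returns_zero():
    pred = np.full((4, 4, 3), 1 / 3, dtype=np.float32)
    out = sc_loss(pred, np.zeros((4, 4), int), np.zeros((4, 4), bool))
    assert out.item() == 0.0


def test_sc_rejects_label_outside_classes():
    pred = np.full((2, 2, 3), 1 / 3, dtype=np.float32)
    with pytest.raises(ValueError):
        sc_loss(pred, np.full((2, 2), 5), np.ones((2, 2), bool))


# -- pathology awareness ----------------------------------------------------

def test_pa_exact_prediction_is_near_zero():
    assert pa_loss(np.array([1.0, 0.0]), np.array([1.0, 0.0])).item() < 1e-5


def test_pa_half_probability_is_ln2():
    assert pa_loss(np.array([0.5]), np.array([1.0])).item() == pytest.approx(
        math.log(2), abs=1e-6)
    assert pa_loss(np.array([0.5]), np.array([0.0])).item() == pytest.approx(
        math.log(2), abs=1e-6)


def test_pa_matches_hand_computed_mean():
    p = np.array([0.9, 0.2, 0.6], dtype=np.float32)
    y = np.array([1.0, 0.0, 1.0], dtype=np.float32)
    want = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
    assert pa_loss(p, y).item() == pytest.approx(want, abs=1e-7)


# -- total ------------------------------------------------------------------

def test_total_with_unit_components_and_default_weights():
    bd = total_loss(1, 1, 1, 1, 1, 1, LossWeights())
    assert bd.total == pytest.approx(13.2)
    assert bd.verify(LossWeights())


def test_total_zero_components():
    assert total_loss(0, 0, 0, 0, 0, 0, LossWeights()).total == 0.0


def test_total_matches_dot_product_on_random_inputs():
    for trial in range(10):
        rng = np.random.default_rng(trial)
        c = rng.random(6)
        w = LossWeights(*rng.random(4))
        bd = total_loss(*c, w)
        want = c[0] + c[1] + np.dot([w.alpha, w.beta, w.gamma, w.iota], c[2:])
        assert bd.total == pytest.approx(want, abs=1e-9)
        assert bd.verify(w, tol=1e-12)


def test_total_rejects_nan_naming_the_term():
    with pytest.raises(ValueError, match="embedding"):
        total_loss(0, 0, 0, float("nan"), 0, 0, LossWeights())


def test_negative_weights_rejected():
    with pytest.raises(ValueError):
        LossWeights(alpha=-1.0)


# -- discriminator ----------------------------------------------------------

def test_patchgan_receptive_field_is_70():
    assert discriminator_receptive_field() == 70
    d = Discriminator(3, np.random.default_rng(0))
    assert d.receptive_field == 70


def test_discriminator_outputs_score_map():
    d = Discriminator(3, np.random.default_rng(0), base_width=4)
    out = d(Tensor(RNG.random((2, 3, 64, 64)).astype(np.float32)))
    assert out.shape[0] == 2 and out.shape[1] == 1
    assert out.shape[2] > 1 and out.shape[3] > 1   # a map, not a scalar


def test_discriminator_gets_gradient_from_fakes():
    """The discriminator term must propagate gradient through D for both the
    real and the (image-detached) fake batch — a D that only ever learns
    from reals collapses to scoring everything as real."""
    d = Discriminator(3, np.random.default_rng(0), base_width=4)
    real = Tensor(RNG.random((1, 3, 64, 64)).astype(np.float32))
    fake_scores_only = d(Tensor(RNG.random((1, 3, 64, 64)).astype(np.float32)))
    _, disc = adversarial_loss_from_scores(d(real), fake_scores_only)
    d.zero_grad()
    disc.backward()
    head_grad = d.convs[-1].weight.grad
    assert head_grad is not None and np.any(head_grad != 0)
    # and the fake contribution alone is nonzero
    d.zero_grad()
    (fake_scores_only ** 2).mean().backward()
    assert np.any(d.convs[-1].weight.grad != 0)
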