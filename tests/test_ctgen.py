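"""Windowed attention, Swin layers, RSTB and the full generator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octstain.ctgen import (Generator, GeneratorConfig, RSTB, SwinLayer,
                            WindowAttention, relative_position_index,
                            window_partition, window_reverse)
from octstain.nn import Tensor

RNG = np.random.default_rng(42)


# -- window partition -------------------------------------------------------

def test_partition_8x8_window4_round_trip():
    grid = Tensor(RNG.random((1, 8, 8, 3)).astype(np.float32))
    windows, info = window_partition(grid, 4)
    assert windows.shape == (4, 16, 3)
    back = window_reverse(windows, info)
    assert np.array_equal(back.data, grid.data)


def test_partition_4x4_window4_tokens_are_row_major():
    grid = Tensor(np.arange(16, dtype=np.float32).reshape(1, 4, 4, 1))
    windows, _ = window_partition(grid, 4)
    assert windows.shape == (1, 16, 1)
    assert np.array_equal(windows.data.ravel(), np.arange(16))


def test_partition_6x6_pads_to_8x8_and_crops_back():
    grid = Tensor(RNG.random((2, 6, 6, 2)).astype(np.float32))
    windows, info = window_partition(grid, 4)
    assert windows.shape == (2 * 4, 16, 2)
    assert (info.padded_h, info.padded_w) == (8, 8)
    # direct index bookkeeping: window (0,0) holds rows 0:4, cols 0:4
    w00 = windows.data[0].reshape(4, 4, 2)
    assert np.array_equal(w00, grid.data[0, :4, :4])
    # padded region is zero: window (1,1) rows 4:8, cols 4:8 -> bottom-right 2x2 zero
    w11 = windows.data[3].reshape(4, 4, 2)
    assert np.array_equal(w11[:2, :2], grid.data[0, 4:6, 4:6])
    assert np.all(w11[2:, :] == 0) and np.all(w11[:, 2:] == 0)
    back = window_reverse(windows, info)
    assert np.array_equal(back.data, grid.data)


def test_partition_without_padding_rejects_indivisible():
    grid = Tensor(np.zeros((1, 6, 6, 1), dtype=np.float32))
    with pytest.raises(ValueError):
        window_partition(grid, 4, pad=False)


@settings(max_examples=20, deadline=None)
@given(h=st.integers(2, 10), w=st.integers(2, 10), win=st.sampled_from([2, 3, 4]))
def test_partition_conserves_tokens(h, w, win):
    """HW tokens in, HW tokens out, for any grid size and window."""
    grid = Tensor(np.random.default_rng(h * 100 + w).random((1, h, w, 2))
                  .astype(np.float32))
    windows, info = window_partition(grid, win)
    assert windows.shape[0] * windows.shape[1] == info.padded_h * info.padded_w
    assert np.array_equal(window_reverse(windows, info).data, grid.data)


# -- window attention -------------------------------------------------------

def _identity_proj(attn: WindowAttention) -> None:
    attn.proj.weight.data = np.eye(attn.proj.weight.shape[0], dtype=np.float32)
    attn.proj.bias.data[:] = 0


def _brute_force_attention(x, pq, pk, pv, bias, scale):
    """Literal three-loop evaluation of SoftMax(Q K^T / sqrt(d) + B) V."""
    n, c = x.shape
    q, k, v = x @ pq, x @ pk, x @ pv
    out = np.zeros_like(v)
    for i in range(n):
        logits = np.array([q[i] @ k[j] * scale + bias[i, j] for j in range(n)])
        e = np.exp(logits - logits.max())
        wgt = e / e.sum()
        for j in range(n):
            out[i] += wgt[j] * v[j]
    return out


def test_attention_matches_brute_force_oracle():
    """>=20 random 4-token single-head windows agree with the literal
    SoftMax(QK^T/sqrt(d)+B)V evaluation within 1e-5."""
    for trial in range(25):
        rng = np.random.default_rng(trial)
        attn = WindowAttention(dim=6, n_heads=1, window=2, rng=rng)
        _identity_proj(attn)
        x = rng.standard_normal((1, 4, 6)).astype(np.float32)
        got = attn(Tensor(x)).data[0]
        idx = relative_position_index(2)
        bias = attn.bias_table.data[idx, 0].reshape(4, 4)
        want = _brute_force_attention(x[0], attn.p_q.weight.data,
                                      attn.p_k.weight.data,
                                      attn.p_v.weight.data,
                                      bias, 1.0 / np.sqrt(6))
        assert np.max(np.abs(got - want)) < 1e-5


def test_single_token_window_returns_value_projection():
    rng = np.random.default_rng(0)
    attn = WindowAttention(dim=4, n_heads=2, window=1, rng=rng)
    _identity_proj(attn)
    attn.bias_table.data[:] = 0
    x = rng.standard_normal((3, 1, 4)).astype(np.float32)
    out = attn(Tensor(x))
    want = x @ attn.p_v.weight.data + attn.p_v.bias.data
    assert np.allclose(out.data, want, atol=1e-6)


def test_attention_output_is_convex_combination_of_values():
    """Softmax weights are a convex combination: outputs (pre-projection)
    stay inside the per-head value range."""
    rng = np.random.default_rng(3)
    attn = WindowAttention(dim=4, n_heads=1, window=2, rng=rng)
    _identity_proj(attn)
    x = rng.standard_normal((2, 4, 4)).astype(np.float32)
    out = attn(Tensor(x)).data
    v = x @ attn.p_v.weight.data + attn.p_v.bias.data
    assert np.all(out <= v.max(axis=1, keepdims=True) + 1e-5)
    assert np.all(out >= v.min(axis=1, keepdims=True) - 1e-5)


def test_relative_bias_is_shared_across_windows():
    """The same bias table entry serves every window: translating a window's
    content to another window slot gives identical attention output."""
    rng = np.random.default_rng(5)
    attn = WindowAttention(dim=6, n_heads=3, window=2, rng=rng)
    block = rng.standard_normal((1, 4, 6)).astype(np.float32)
    two = np.concatenate([block, block], axis=0)
    out = attn(Tensor(two)).data
    assert np.allclose(out[0], out[1], atol=1e-6)


# -- STL / RSTB -------------------------------------------------------------

def _zero_stl(stl: SwinLayer) -> None:
    stl.attn.proj.weight.data[:] = 0
    stl.attn.proj.bias.data[:] = 0
    stl.mlp.fc2.weight.data[:] = 0
    stl.mlp.fc2.bias.data[:] = 0


def test_stl_with_zeroed_projections_is_identity():
    rng = np.random.default_rng(7)
    stl = SwinLayer(dim=6, n_heads=2, window=2, shift=0, mlp_ratio=2.0, rng=rng)
    _zero_stl(stl)
    x = Tensor(rng.random((1, 4, 4, 6)).astype(np.float32))
    assert np.allclose(stl(x).data, x.data, atol=1e-7)


def test_stl_preserves_shape():
    rng = np.random.default_rng(8)
    stl = SwinLayer(dim=6, n_heads=2, window=2, shift=1, mlp_ratio=2.0, rng=rng)
    x = Tensor(rng.random((2, 6, 6, 6)).astype(np.float32))
    assert stl(x).shape == (2, 6, 6, 6)


def test_shifted_windows_change_the_output():
    rng = np.random.default_rng(9)
    plain = SwinLayer(dim=6, n_heads=2, window=2, shift=0, mlp_ratio=2.0,
                      rng=np.random.default_rng(9))
    shifted = SwinLayer(dim=6, n_heads=2, window=2, shift=1, mlp_ratio=2.0,
                        rng=np.random.default_rng(9))
    x = Tensor(rng.random((1, 4, 4, 6)).astype(np.float32))
    assert not np.allclose(plain(x).data, shifted(x).data, atol=1e-6)


def test_rstb_identity_conv_and_zeroed_stls_pass_through():
    rng = np.random.default_rng(10)
    rstb = RSTB(dim=6, n_heads=2, window=2, n_stl=2, mlp_ratio=2.0, rng=rng)
    for stl in rstb.stls:
        _zero_stl(stl)
    rstb.conv.weight.data[:] = 0
    for c in range(6):
        rstb.conv.weight.data[c, c, 1, 1] = 1.0       # Dirac kernel
    rstb.conv.bias.data[:] = 0
    x = Tensor(rng.random((1, 4, 4, 6)).astype(np.float32))
    assert np.allclose(rstb(x).data, x.data, atol=1e-6)


def test_rstb_matches_hand_chained_evaluation():
    """Conv(F_STL + T_IN) == conv applied to the STL-chain output."""
    rng = np.random.default_rng(11)
    rstb = RSTB(dim=6, n_heads=1, window=2, n_stl=1, mlp_ratio=2.0, rng=rng)
    x = Tensor(rng.random((1, 4, 4, 6)).astype(np.float32))
    got = rstb(x).data
    chained = rstb.stls[0](x)
    want = rstb.conv(chained.transpose(0, 3, 1, 2)).transpose(0, 2, 3, 1).data
    assert np.max(np.abs(got - want)) < 1e-5
    assert got.shape == x.shape


# -- generator --------------------------------------------------------------

def test_generator_oct_to_he_contract(tiny_config):
    gen = Generator(tiny_config, np.random.default_rng(0))
    x = Tensor(RNG.random((2, 1, 16, 16)).astype(np.float32))
    out = gen(x)
    assert out.translated.shape == (2, 3, 16, 16)
    assert out.translated.data.min() >= 0 and out.translated.data.max() <= 1
    assert [lv.shape[2] for lv in out.pyramid] == [8, 4, 2]
    assert out.scpa is not None


def test_generator_he_to_oct_channels(tiny_config):
    from dataclasses import replace
    cfg = replace(tiny_config, in_channels=3, out_channels=1)
    gen = Generator(cfg, np.random.default_rng(0))
    out = gen(Tensor(RNG.random((1, 3, 16, 16)).astype(np.float32)))
    assert out.translated.shape == (1, 1, 16, 16)


def test_scpa_concatenation_path_is_live(tiny_config):
    gen = Generator(tiny_config, np.random.default_rng(0))
    x = Tensor(RNG.random((1, 1, 16, 16)).astype(np.float32))
    with_scpa = gen(x, scpa_on=True).translated.data
    without = gen(x, scpa_on=False).translated.data
    assert not np.allclose(with_scpa, without, atol=1e-6)


def test_generator_rejects_wrong_input_size(tiny_config):
    gen = Generator(tiny_config, np.random.default_rng(0))
    with pytest.raises(ValueError):
        gen(Tensor(np.zeros((1, 1, 24, 24), dtype=np.float32)))


def test_every_parameter_receives_gradient(tiny_config):
    """No dead branches: every trainable parameter gets a nonzero gradient
    for at least one random batch (SCPA concatenation included)."""
    gen = Generator(tiny_config, np.random.default_rng(0))
    params = dict(gen.named_parameters())
    nonzero = {name: False for name in params}
    for trial in range(3):
        gen.zero_grad()
        x = Tensor(np.random.default_rng(trial).random((2, 1, 16, 16))
                   .astype(np.float32))
        out = gen(x)
        # quadratic in the segmentation so its (constant-sum) softmax still
        # passes gradient to the class-embedding branch
        loss = (out.translated.sum() + (out.scpa.segmentation ** 2).sum()
                + out.scpa.pathology_score.sum())
        loss.backward()
        for name, p in params.items():
            if p.grad is not None and np.any(p.grad != 0):
                nonzero[name] = True
    dead = [n for n, ok in nonzero.items() if not ok]
    assert not dead, f"parameters with no gradient: {dead[:5]}"


def test_config_invariants():
    with pytest.raises(ValueError):
        GeneratorConfig(d_model=10, n_heads=3)
    with pytest.raises(ValueError):
        GeneratorConfig(image_size=30)        # not divisible by 2**n_scales
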