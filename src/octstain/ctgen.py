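"""Convolutional transformer generator for unpaired domain translation.

Each generator (OCT->H&E and H&E->OCT) is a U-Net-like encoder/decoder:
three stride-2 convolutions extract a multi-scale feature pyramid, the
deepest grid is refined by a Swin-style transformer block (STB: a stack of
residual Swin transformer sub-blocks, RSTB, each a chain of Swin
transformer layers, STL, followed by a 3x3 convolution), and the SCPA
head's patch embeddings are concatenated channel-wise before the
transpose-convolution up-sampling path.  A sigmoid head keeps outputs in
[0, 1].

Windowed attention follows the Swin convention: non-overlapping
``window x window`` token windows, a learnable relative-position bias per
head shared across windows, pre-norm residual layers, and a cyclic shift of
``window // 2`` with masked attention on every second STL.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import NamedTuple

import numpy as np

from . import nn
from .nn import Tensor
from .scpa import SCPAConfig, SCPAModule, SCPAOutput, nearest_upsample

__all__ = ["GeneratorConfig", "Generator", "GeneratorOutput",
           "WindowAttention", "SwinLayer", "RSTB",
           "window_partition", "window_reverse", "relative_position_index"]


class WindowInfo(NamedTuple):
    batch: int
    height: int
    width: int
    padded_h: int
    padded_w: int
    window: int


def window_partition(grid: Tensor, window: int,
                     pad: bool = True) -> tuple[Tensor, WindowInfo]:
    """(B, H, W, C) -> (B * nW, window**2, C) non-overlapping window tokens.

    Sides not divisible by ``window`` are zero-padded symmetrically on the
    bottom/right when ``pad=True``; otherwise this is an error.  Token order
    inside a window is row-major.
    """
    b, h, w, c = grid.shape
    ph = (window - h % window) % window
    pw = (window - w % window) % window
    if (ph or pw) and not pad:
        raise ValueError(f"grid {h}x{w} not divisible by window {window}")
    if ph or pw:
        grid = grid.transpose(0, 3, 1, 2).pad2d((0, ph), (0, pw)).transpose(0, 2, 3, 1)
    hp, wp = h + ph, w + pw
    x = grid.reshape(b, hp // window, window, wp // window, window, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    windows = x.reshape(b * (hp // window) * (wp // window), window * window, c)
    return windows, WindowInfo(b, h, w, hp, wp, window)


def window_reverse(windows: Tensor, info: WindowInfo) -> Tensor:
    """Inverse of :func:`window_partition`, cropping any padding."""
    b, h, w, hp, wp, window = info
    c = windows.shape[-1]
    x = windows.reshape(b, hp // window, wp // window, window, window, c)
    x = x.transpose(0, 1, 3, 2, 4, 5).reshape(b, hp, wp, c)
    if hp != h or wp != w:
        x = x[:, :h, :w, :]
    return x


def relative_position_index(window: int) -> np.ndarray:
    """Flattened (N*N,) index into the (2w-1)**2 relative-bias table."""
    coords = np.stack(np.meshgrid(np.arange(window), np.arange(window),
                                  indexing="ij")).reshape(2, -1)
    rel = coords[:, :, None] - coords[:, None, :]          # (2, N, N)
    rel = rel.transpose(1, 2, 0) + (window - 1)
    return (rel[..., 0] * (2 * window - 1) + rel[..., 1]).reshape(-1)


class WindowAttention(nn.Module):
    """Multi-head self-attention inside a window with relative position bias.

    The projections P_Q, P_K, P_V and the bias table are shared across
    windows; the bias B has shape (N^2, N^2) per head, indexed by 2-D
    relative token offsets.
    """

    def __init__(self, dim: int, n_heads: int, window: int,
                 rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.window = window
        self.p_q = nn.Linear(dim, dim, rng)
        self.p_k = nn.Linear(dim, dim, rng)
        self.p_v = nn.Linear(dim, dim, rng)
        self.proj = nn.Linear(dim, dim, rng)
        self.bias_table = nn.Parameter(
            0.02 * rng.standard_normal(((2 * window - 1) ** 2, n_heads)))
        self._bias_index = relative_position_index(window)

    def forward(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        b_, n, c = x.shape
        h, d = self.n_heads, self.head_dim

        def split(t: Tensor) -> Tensor:
            return t.reshape(b_, n, h, d).transpose(0, 2, 1, 3)

        q, k, v = split(self.p_q(x)), split(self.p_k(x)), split(self.p_v(x))
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d))
        bias = self.bias_table[self._bias_index]           # (N*N, heads)
        bias = bias.reshape(n, n, h).transpose(2, 0, 1).reshape(1, h, n, n)
        logits = logits + bias
        if mask is not None:
            nw = mask.shape[0]
            logits = logits.reshape(b_ // nw, nw, h, n, n) + mask[None, :, None]
            logits = logits.reshape(b_, h, n, n)
        attn = logits.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b_, n, c)
        return self.proj(out)


def _shift_mask(hp: int, wp: int, window: int, shift: int) -> np.ndarray:
    """Additive attention mask for shifted windows (standard Swin recipe)."""
    img = np.zeros((hp, wp), dtype=np.int64)
    cnt = 0
    for hs in (slice(0, -window), slice(-window, -shift), slice(-shift, None)):
        for ws in (slice(0, -window), slice(-window, -shift), slice(-shift, None)):
            img[hs, ws] = cnt
            cnt += 1
    x = img.reshape(hp // window, window, wp // window, window)
    x = x.transpose(0, 2, 1, 3).reshape(-1, window * window)
    diff = x[:, None, :] != x[:, :, None]
    return np.where(diff, -100.0, 0.0).astype(np.float32)


class SwinLayer(nn.Module):
    """One STL: LN -> (shifted) window MHA -> residual, LN -> MLP -> residual."""

    def __init__(self, dim: int, n_heads: int, window: int, shift: int,
                 mlp_ratio: float, rng: np.random.Generator):
        self.window = window
        self.shift = shift
        self.norm1 = nn.LayerNorm(dim)
        self.attn = WindowAttention(dim, n_heads, window, rng)
        self.norm2 = nn.LayerNorm(dim)
        self.mlp = nn.Mlp(dim, int(dim * mlp_ratio), rng)
        self._mask_cache: dict[tuple[int, int], np.ndarray] = {}

    def forward(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        y = self.norm1(x)
        mask = None
        # a window covering the whole grid leaves nothing to shift across
        shift_active = self.shift and min(h, w) > self.window
        if shift_active:
            y = y.roll((-self.shift, -self.shift), (1, 2))
            hp = h + (self.window - h % self.window) % self.window
            wp = w + (self.window - w % self.window) % self.window
            key = (hp, wp)
            if key not in self._mask_cache:
                self._mask_cache[key] = _shift_mask(hp, wp, self.window, self.shift)
            mask = self._mask_cache[key]
        windows, info = window_partition(y, self.window)
        attended = self.attn(windows, mask=mask)
        y = window_reverse(attended, info)
        if shift_active:
            y = y.roll((self.shift, self.shift), (1, 2))
        x = x + y
        return x + self.mlp(self.norm2(x))


class RSTB(nn.Module):
    """Residual Swin transformer sub-block: T_out = Conv3x3(STL_chain(T_in)).

    Because every STL is residual (x plus its attention/MLP contributions),
    the chain output equals T_in plus the accumulated STL features, so the
    convolution sees the sum of the input and the transformer features.
    """

    def __init__(self, dim: int, n_heads: int, window: int, n_stl: int,
                 mlp_ratio: float, rng: np.random.Generator):
        self.stls = [SwinLayer(dim, n_heads, window,
                               shift=0 if i % 2 == 0 else window // 2,
                               mlp_ratio=mlp_ratio, rng=rng)
                     for i in range(n_stl)]
        self.conv = nn.Conv2d(dim, dim, 3, rng, padding=1)

    def forward(self, x: Tensor) -> Tensor:
        y = x
        for stl in self.stls:
            y = stl(y)
        y = y.transpose(0, 3, 1, 2)        # NHWC -> NCHW for the conv
        y = self.conv(y)
        return y.transpose(0, 2, 3, 1)


@dataclass(frozen=True)
class GeneratorConfig:
    """Architecture of one translation generator.

    ``image_size`` fixes the training/inference patch side; larger images
    are handled by tiling at inference time.  The deepest feature grid is
    ``image_size / 2**n_scales`` on a side; it must be divisible by the
    SCPA patch size, and window attention pads when it is not divisible by
    ``window_size``.
    """

    in_channels: int = 1
    out_channels: int = 3
    image_size: int = 64
    base_width: int = 32
    n_scales: int = 3
    window_size: int = 4
    d_model: int = 96
    n_rstb: int = 2
    n_stl_per_rstb: int = 2
    n_heads: int = 3
    mlp_ratio: float = 4.0
    scpa_patch: int = 2
    scpa_d: int = 96
    scpa_depth: int = 2

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.image_size % (2 ** self.n_scales):
            raise ValueError("image_size must be divisible by 2**n_scales")
        if (self.image_size // 2 ** self.n_scales) % self.scpa_patch:
            raise ValueError("deepest grid must be divisible by scpa_patch")

    @property
    def deep_grid(self) -> int:
        return self.image_size // 2 ** self.n_scales

    @classmethod
    def test_preset(cls, in_channels: int = 1, out_channels: int = 3,
                    image_size: int = 64) -> "GeneratorConfig":
        """Small CPU-friendly preset used throughout the test suite."""
        return cls(in_channels=in_channels, out_channels=out_channels,
                   image_size=image_size, base_width=8, window_size=4,
                   d_model=24, n_rstb=1, n_stl_per_rstb=2, n_heads=3,
                   mlp_ratio=2.0, scpa_patch=1, scpa_d=24, scpa_depth=2)

    @classmethod
    def paper_preset(cls, in_channels: int = 1, out_channels: int = 3) -> "GeneratorConfig":
        """Full-size preset (368x368 patches, window 8)."""
        return cls(in_channels=in_channels, out_channels=out_channels,
                   image_size=368, base_width=32, window_size=8,
                   d_model=96, n_rstb=2, n_stl_per_rstb=2, n_heads=3,
                   mlp_ratio=4.0, scpa_patch=2, scpa_d=96, scpa_depth=2)


@dataclass
class GeneratorOutput:
    translated: Tensor            # (B, out_ch, H, W) in [0, 1]
    pyramid: list[Tensor]         # encoder features, one per scale
    scpa: SCPAOutput | None       # segmentation / pathology / z_M handoff
    bottleneck: Tensor            # deepest encoder features (embedding loss)


class Generator(nn.Module):
    """U-Net + STB + SCPA translation generator."""

    def __init__(self, config: GeneratorConfig, rng: np.random.Generator):
        cfg = config
        self.config = cfg
        w = cfg.base_width
        self.stem = nn.Conv2d(cfg.in_channels, w, 3, rng, padding=1)
        self.enc1 = nn.Conv2d(w, 2 * w, 3, rng, stride=2, padding=1)
        self.enc2 = nn.Conv2d(2 * w, 4 * w, 3, rng, stride=2, padding=1)
        self.enc3 = nn.Conv2d(4 * w, 4 * w, 3, rng, stride=2, padding=1)
        self.norm_stem = nn.InstanceNorm2d(w)
        self.norm1 = nn.InstanceNorm2d(2 * w)
        self.norm2 = nn.InstanceNorm2d(4 * w)
        self.norm3 = nn.InstanceNorm2d(4 * w)

        self.proj_stb = nn.Conv2d(4 * w, cfg.d_model, 1, rng)
        self.rstbs = [RSTB(cfg.d_model, cfg.n_heads, cfg.window_size,
                           cfg.n_stl_per_rstb, cfg.mlp_ratio, rng)
                      for _ in range(cfg.n_rstb)]

        self.scpa = SCPAModule(SCPAConfig(
            in_channels=4 * w, grid_size=cfg.deep_grid, patch=cfg.scpa_patch,
            d=cfg.scpa_d, n_heads=cfg.n_heads, mlp_ratio=2.0,
            upsample_to=cfg.image_size), rng)

        self.merge = nn.Conv2d(cfg.d_model + cfg.scpa_d, 4 * w, 3, rng, padding=1)
        self.norm_m = nn.InstanceNorm2d(4 * w)
        self.up3 = nn.ConvTranspose2d(4 * w, 2 * w, 2, rng, stride=2)
        self.norm_u3 = nn.InstanceNorm2d(2 * w)
        self.up2 = nn.ConvTranspose2d(2 * w + 4 * w, w, 2, rng, stride=2)
        self.norm_u2 = nn.InstanceNorm2d(w)
        self.up1 = nn.ConvTranspose2d(w + 2 * w, w, 2, rng, stride=2)
        self.norm_u1 = nn.InstanceNorm2d(w)
        self.head = nn.Conv2d(w + w, cfg.out_channels, 3, rng, padding=1)

    # -- passes --------------------------------------------------------------

    def encode(self, x: Tensor) -> list[Tensor]:
        """Multi-scale feature pyramid; the last level is the bottleneck."""
        s = self.norm_stem(self.stem(x)).relu()
        e1 = self.norm1(self.enc1(s)).relu()
        e2 = self.norm2(self.enc2(e1)).relu()
        e3 = self.norm3(self.enc3(e2)).relu()
        return [s, e1, e2, e3]

    def embed(self, x: Tensor) -> Tensor:
        """Bottleneck embedding (deepest encoder features), for the
        embedding-consistency loss."""
        return self.encode(x)[-1]

    def stb(self, bottleneck: Tensor) -> Tensor:
        """Swin transformer block over the deepest grid (NCHW in/out)."""
        t = self.proj_stb(bottleneck).transpose(0, 2, 3, 1)   # NHWC
        for rstb in self.rstbs:
            t = rstb(t)
        return t.transpose(0, 3, 1, 2)

    def forward(self, x: Tensor, scpa_on: bool = True) -> GeneratorOutput:
        if x.shape[2] != self.config.image_size or x.shape[3] != self.config.image_size:
            raise ValueError(
                f"input {x.shape[2]}x{x.shape[3]} does not match configured "
                f"image_size {self.config.image_size}; tile larger inputs")
        s, e1, e2, e3 = self.encode(x)
        t = self.stb(e3)

        scpa_out: SCPAOutput | None = None
        if scpa_on:
            scpa_out = self.scpa(e3)
            side = self.config.deep_grid // self.config.scpa_patch
            zgrid = scpa_out.z_m.reshape(x.shape[0], side, side, self.config.scpa_d)
            zgrid = nearest_upsample(zgrid, self.config.scpa_patch)
            zgrid = zgrid.transpose(0, 3, 1, 2)               # NCHW
        else:
            b = x.shape[0]
            g = self.config.deep_grid
            zgrid = Tensor(np.zeros((b, self.config.scpa_d, g, g), dtype=np.float32))

        m = self.norm_m(self.merge(nn.concat([t, zgrid], axis=1))).relu()
        u3 = self.norm_u3(self.up3(m)).relu()
        u2 = self.norm_u2(self.up2(nn.concat([u3, e2], axis=1))).relu()
        u1 = self.norm_u1(self.up1(nn.concat([u2, e1], axis=1))).relu()
        out = self.head(nn.concat([u1, s], axis=1)).sigmoid()
        return GeneratorOutput(translated=out, pyramid=[e1, e2, e3],
                               scpa=scpa_out, bottleneck=e3)

    # -- inference convenience ----------------------------------------------

    def translate(self, image: np.ndarray) -> np.ndarray:
        """numpy [0,1] image (H, W) or (H, W, C) -> translated numpy image."""
        img = np.asarray(image, dtype=np.float32)
        if img.ndim == 2:
            img = img[..., None]
        x = Tensor(img.transpose(2, 0, 1)[None])
        y = self.forward(x).translated.data[0].transpose(1, 2, 0)
        return y.squeeze()

    def config_dict(self) -> dict:
        return asdict(self.config)
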