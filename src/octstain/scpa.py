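"""Structure-constraint and pathology-awareness (SCPA) head.

A small transformer encoder–decoder over patches of the generator's deepest
feature grid.  Three jobs:

1. **Structural constraint** — segment the coronary wall into K=3 layers
   (intima, media, adventitia).  Patch embeddings ``z_M`` and decoded class
   embeddings ``c`` meet in a scalar product: segmentation logits are
   ``z_M @ c.T`` per patch, upsampled (nearest-neighbour on logits) to
   image resolution and softmaxed per pixel.
2. **Pathology awareness** — a two-level MLP on mean-pooled ``z_M`` scores
   the image as normal vs pathological (sigmoid probability).
3. **Feature handoff** — ``z_M`` itself is returned so the generator can
   concatenate it with its transformer features before up-sampling.

The decoder follows the Segmenter recipe: patch tokens and the three
randomly initialised learnable class embeddings are processed jointly and
split afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["SCPAConfig", "SCPAOutput", "SCPAModule", "TransformerLayer",
           "MultiheadAttention", "patchify", "nearest_upsample",
           "segmentation_from_embeddings"]

N_LAYER_CLASSES = 3  # intima, media, adventitia


def patchify(features: Tensor, patch: int) -> Tensor:
    """(B, C, H, W) -> (B, N, patch*patch*C) flattened patches, row-major.

    Patch k (row-major over the patch grid) is the (C, patch, patch) block
    at that location, flattened channel-first.
    """
    b, c, h, w = features.shape
    if h % patch or w % patch:
        raise ValueError(f"feature grid {h}x{w} not divisible by patch {patch}")
    hp, wp = h // patch, w // patch
    x = features.reshape(b, c, hp, patch, wp, patch)
    x = x.transpose(0, 2, 4, 1, 3, 5)            # (B, hp, wp, C, P, P)
    return x.reshape(b, hp * wp, c * patch * patch)


def nearest_upsample(grid: Tensor, factor: int) -> Tensor:
    """(B, H, W, C) -> (B, H*f, W*f, C) by nearest-neighbour repetition."""
    b, h, w, c = grid.shape
    x = grid.reshape(b, h, 1, w, 1, c)
    ones = np.ones((1, 1, factor, 1, factor, 1), dtype=np.float32)
    return (x * ones).reshape(b, h * factor, w * factor, c)


class MultiheadAttention(nn.Module):
    """Standard full multi-head self-attention over a token sequence."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.q = nn.Linear(dim, dim, rng)
        self.k = nn.Linear(dim, dim, rng)
        self.v = nn.Linear(dim, dim, rng)
        self.proj = nn.Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        b, n, c = x.shape
        h, d = self.n_heads, self.head_dim

        def split(t: Tensor) -> Tensor:
            return t.reshape(b, n, h, d).transpose(0, 2, 1, 3)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d))
        attn = logits.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, n, c)
        return self.proj(out)


class TransformerLayer(nn.Module):
    """Pre-norm residual transformer layer: x + MHA(LN(x)), then + MLP(LN(.))."""

    def __init__(self, dim: int, n_heads: int, mlp_ratio: float,
                 rng: np.random.Generator):
        self.norm1 = nn.LayerNorm(dim)
        self.attn = MultiheadAttention(dim, n_heads, rng)
        self.norm2 = nn.LayerNorm(dim)
        self.mlp = nn.Mlp(dim, int(dim * mlp_ratio), rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.mlp(self.norm2(x))


@dataclass(frozen=True)
class SCPAConfig:
    in_channels: int          # channels of the feature grid fed to the head
    grid_size: int            # side of that (square) feature grid
    patch: int = 2
    d: int = 96
    n_heads: int = 3
    depth_encoder: int = 2
    depth_decoder: int = 2
    mlp_ratio: float = 2.0
    upsample_to: int = 64     # output segmentation side (image resolution)


@dataclass
class SCPAOutput:
    segmentation: Tensor      # (B, H, W, K) per-pixel class probabilities
    pathology_score: Tensor   # (B,) sigmoid probability of "pathological"
    z_m: Tensor               # (B, N, d) decoder patch embeddings
    class_vectors: Tensor     # (B, K, d) decoded class embeddings


def segmentation_from_embeddings(z_m: Tensor, c: Tensor, side: int,
                                 upsample_to: int) -> Tensor:
    """Scalar-product segmentation head.

    Logits are ``z_M @ c.T`` per patch, laid out on the (side x side) patch
    grid, nearest-upsampled to ``upsample_to`` pixels and softmaxed per
    pixel; returns (B, H, W, K) probabilities.
    """
    b, k, _ = c.shape
    logits = z_m @ c.transpose(0, 2, 1)                    # (B, N, K)
    grid = logits.reshape(b, side, side, k)
    return nearest_upsample(grid, upsample_to // side).softmax(axis=-1)


class SCPAModule(nn.Module):
    def __init__(self, config: SCPAConfig, rng: np.random.Generator):
        cfg = config
        if cfg.grid_size % cfg.patch:
            raise ValueError("grid_size must be divisible by patch")
        self.config = cfg
        n_tokens = (cfg.grid_size // cfg.patch) ** 2
        self.embed = nn.Linear(cfg.patch * cfg.patch * cfg.in_channels, cfg.d, rng)
        self.pos = nn.Parameter(0.02 * rng.standard_normal((n_tokens, cfg.d)))
        self.encoder = [TransformerLayer(cfg.d, cfg.n_heads, cfg.mlp_ratio, rng)
                        for _ in range(cfg.depth_encoder)]
        self.cls_embed = nn.Parameter(
            0.02 * rng.standard_normal((N_LAYER_CLASSES, cfg.d)))
        self.decoder = [TransformerLayer(cfg.d, cfg.n_heads, cfg.mlp_ratio, rng)
                        for _ in range(cfg.depth_decoder)]
        self.cls_mlp = nn.Mlp(cfg.d, cfg.d, rng, out_dim=1)

    def embed_tokens(self, features: Tensor) -> Tensor:
        """Patchify, linearly embed and add position embeddings: z0 = x0 + pos."""
        x0 = self.embed(patchify(features, self.config.patch))
        return x0 + self.pos

    def forward(self, features: Tensor) -> SCPAOutput:
        cfg = self.config
        b = features.shape[0]
        z = self.embed_tokens(features)
        for layer in self.encoder:
            z = layer(z)                                   # z_L
        n = z.shape[1]
        cls = self.cls_embed.reshape(1, N_LAYER_CLASSES, cfg.d) * np.ones(
            (b, 1, 1), dtype=np.float32)
        tokens = nn.concat([z, cls], axis=1)
        for layer in self.decoder:
            tokens = layer(tokens)
        z_m = tokens[:, :n]                                # (B, N, d)
        c = tokens[:, n:]                                  # (B, K, d)

        side = cfg.grid_size // cfg.patch
        seg = segmentation_from_embeddings(z_m, c, side, cfg.upsample_to)

        pooled = z_m.mean(axis=1)                          # (B, d)
        score = self.cls_mlp(pooled).reshape(b).sigmoid()
        return SCPAOutput(segmentation=seg, pathology_score=score, z_m=z_m,
                          class_vectors=c)
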