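"""Trainable layers on top of the autodiff engine."""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Module", "Parameter", "Linear", "Conv2d", "ConvTranspose2d",
    "LayerNorm", "InstanceNorm2d", "Mlp", "Sequential",
]


class Parameter(Tensor):
    """A leaf tensor updated by an optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal module container: parameter discovery, state dicts, train mode."""

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters(prefix)}

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        own = dict(self.named_parameters(prefix))
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)[:3]} "
                           f"extra={sorted(extra)[:3]}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


def _kaiming(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
    bound = math.sqrt(1.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        self.weight = Parameter(_kaiming(rng, in_features, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        self.stride, self.padding = stride, padding
        self.weight = Parameter(_kaiming(rng, in_ch * k * k, (out_ch, in_ch, k, k)))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator,
                 stride: int = 2, padding: int = 0, bias: bool = True):
        self.stride, self.padding = stride, padding
        self.weight = Parameter(_kaiming(rng, in_ch * k * k, (in_ch, out_ch, k, k)))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d(x, self.weight, self.bias, self.stride, self.padding)


class LayerNorm(Module):
    """Normalisation over the trailing channel axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.eps = eps
        self.weight = Parameter(np.ones(dim, dtype=np.float32))
        self.bias = Parameter(np.zeros(dim, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        shape = (1,) * (x.ndim - 1) + (self.weight.shape[0],)
        return F.normalize(x, (x.ndim - 1,), self.weight, self.bias,
                           self.eps, shape)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalisation over spatial axes (NCHW)."""

    def __init__(self, channels: int, eps: float = 1e-5, affine: bool = True):
        self.eps = eps
        self.weight = Parameter(np.ones(channels, dtype=np.float32)) if affine else None
        self.bias = Parameter(np.zeros(channels, dtype=np.float32)) if affine else None

    def forward(self, x: Tensor) -> Tensor:
        shape = (1, x.shape[1], 1, 1)
        return F.normalize(x, (2, 3), self.weight, self.bias, self.eps, shape)


class Mlp(Module):
    """Two-level MLP with GELU, as used inside transformer layers."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator,
                 out_dim: int | None = None):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, out_dim if out_dim is not None else dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x
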