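"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine: each :class:`Tensor` wraps a float32 ndarray and
remembers how it was produced, so a single :meth:`Tensor.backward` call
propagates gradients to every leaf with ``requires_grad=True``.  The op set
is exactly what the virtual-staining networks need (dense/conv/transposed
conv layers, layer normalisation, windowed attention, the GAN losses) — it
is not a general framework.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np
from scipy import special as _special

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A float32 ndarray plus the bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make numpy defer to Tensor's reflected operators (ndarray * Tensor etc.)
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic protocol ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autograd ------------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        # iterative topological order over the tape (graphs can be deep)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = (np.asarray(grad, dtype=np.float32) if self.grad is None
                     else self.grad + np.asarray(grad, dtype=np.float32))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node.grad = None  # intermediate: free once consumed

    def _acc(self, parent: "Tensor", g: np.ndarray) -> None:
        """Accumulate gradient ``g`` onto ``parent`` during a backward pass."""
        if not parent.requires_grad:
            return
        parent.grad = g if parent.grad is None else parent.grad + g

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g: np.ndarray, out=None) -> None:
            out._acc(self, _unbroadcast(g, self.shape))
            out._acc(other, _unbroadcast(g, other.shape))

        out = self._make(out_data, (self, other), lambda g: backward(g, out))
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g: np.ndarray, out=None) -> None:
            out._acc(self, -g)

        out = self._make(-self.data, (self,), lambda g: backward(g, out))
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g: np.ndarray, out=None) -> None:
            out._acc(self, _unbroadcast(g * other.data, self.shape))
            out._acc(other, _unbroadcast(g * self.data, other.shape))

        out = self._make(out_data, (self, other), lambda g: backward(g, out))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g: np.ndarray, out=None) -> None:
            out._acc(self, _unbroadcast(g / other.data, self.shape))
            out._acc(other, _unbroadcast(-g * self.data / (other.data ** 2), other.shape))

        out = self._make(out_data, (self, other), lambda g: backward(g, out))
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) / self

    def __pow__(self, p: float) -> "Tensor":
        out_data = self.data ** p

        def backward(g: np.ndarray, out=None) -> None:
            out._acc(self, g * p * self.data ** (p - 1))

        out = self._make(out_data, (self,), lambda g: backward(g, out))
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g: np.ndarray, out=None) -> None:
            a, b = self.data, other.data
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            out._acc(self, _unbroadcast(ga, self.shape))
            out._acc(other, _unbroadcast(gb, other.shape))

        out = self._make(out_data, (self, other), lambda g: backward(g, out))
        return out

    # -- shape ops -----------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def backward(g: np.ndarray, out=None) -> None:
            out._acc(self, g.reshape(self.shape))

        out = self._make(out_data, (self,), lambda g: backward(g, out))
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g: np.ndarray, out=None) -> None:
            out._acc(self, g.transpose(inv))

        out = self._make(out_data, (self,), lambda g: backward(g, out))
        return out

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]

        def backward(g: np.ndarray, out=None) -> None:
            gx = np.zeros_like(self.data)
            np.add.at(gx, idx, g)
            out._acc(self, gx)

        out = self._make(out_data, (self,), lambda g: backward(g, out))
        return out

    def pad2d(self, pad_h: tuple[int, int], pad_w: tuple[int, int]) -> "Tensor":
        """Zero-pad the last two axes."""
        width = [(0, 0)] * (self.ndim - 2) + [pad_h, pad_w]
        out_data = np.pad(self.data, width)
        sl = tuple([slice(None)] * (self.ndim - 2)
                   + [slice(pad_h[0], out_data.shape[-2] - pad_h[1]),
                      slice(pad_w[0], out_data.shape[-1] - pad_w[1])])

        def backward(g: np.ndarray, out=None) -> None:
            out._acc(self, g[sl])

        out = self._make(out_data, (self,), lambda g: backward(g, out))
        return out

    def roll(self, shifts: tuple[int, int], axes: tuple[int, int]) -> "Tensor":
        out_data = np.roll(self.data, shifts, axis=axes)
        neg = tuple(-s for s in shifts)

        def backward(g: np.ndarray, out=None) -> None:
            out._acc(self, np.roll(g, neg, axis=axes))

        out = self._make(out_data, (self,), lambda g: backward(g, out))
        return out

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g: np.ndarray, out=None) -> None:
            if axis is None:
                gx = np.broadcast_to(g, self.shape).astype(np.float32)
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                gx = np.broadcast_to(g, self.shape).astype(np.float32)
            out._acc(self, gx.copy())

        out = self._make(out_data, (self,), lambda g: backward(g, out))
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.size
        else:
            ax = (axis,) if isinstance(axis, int) else tuple(axis)
            n = 1
            for a in ax:
                n *= self.shape[a]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -----------------------------------------

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g: np.ndarray, out=None) -> None:
            out._acc(self, g * out_data)

        out = self._make(out_data, (self,), lambda g: backward(g, out))
        return out

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def backward(g: np.ndarray, out=None) -> None:
            out._acc(self, g / self.data)

        out = self._make(out_data, (self,), lambda g: backward(g, out))
        return out

    def sqrt(self) -> "Tensor":
        return self ** 0.5

    def abs(self) -> "Tensor":
        out_data = np.abs(self.data)
        sign = np.sign(self.data).astype(np.float32)

        def backward(g: np.ndarray, out=None) -> None:
            out._acc(self, g * sign)

        out = self._make(out_data, (self,), lambda g: backward(g, out))
        return out

    def sigmoid(self) -> "Tensor":
        out_data = _special.expit(self.data).astype(np.float32)

        def backward(g: np.ndarray, out=None) -> None:
            out._acc(self, g * out_data * (1.0 - out_data))

        out = self._make(out_data, (self,), lambda g: backward(g, out))
        return out

    def relu(self) -> "Tensor":
        mask = (self.data > 0)
        out_data = np.where(mask, self.data, 0.0).astype(np.float32)

        def backward(g: np.ndarray, out=None) -> None:
            out._acc(self, g * mask)

        out = self._make(out_data, (self,), lambda g: backward(g, out))
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        mask = (self.data > 0)
        out_data = np.where(mask, self.data, slope * self.data).astype(np.float32)

        def backward(g: np.ndarray, out=None) -> None:
            out._acc(self, g * np.where(mask, 1.0, slope).astype(np.float32))

        out = self._make(out_data, (self,), lambda g: backward(g, out))
        return out

    def gelu(self) -> "Tensor":
        """Exact GELU: x * Phi(x) with the Gaussian CDF via erf."""
        x = self.data
        phi = 0.5 * (1.0 + _special.erf(x / math.sqrt(2.0)))
        out_data = (x * phi).astype(np.float32)
        pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
        deriv = (phi + x * pdf).astype(np.float32)

        def backward(g: np.ndarray, out=None) -> None:
            out._acc(self, g * deriv)

        out = self._make(out_data, (self,), lambda g: backward(g, out))
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient is passed through only inside the range."""
        out_data = np.clip(self.data, lo, hi)
        mask = ((self.data >= lo) & (self.data <= hi)).astype(np.float32)

        def backward(g: np.ndarray, out=None) -> None:
            out._acc(self, g * mask)

        out = self._make(out_data, (self,), lambda g: backward(g, out))
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = (e / e.sum(axis=axis, keepdims=True)).astype(np.float32)

        def backward(g: np.ndarray, out=None) -> None:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            out._acc(self, out_data * (g - dot))

        out = self._make(out_data, (self,), lambda g: backward(g, out))
        return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray, out=None) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            out._acc(t, g[tuple(sl)])

    out = Tensor._make(out_data, tensors, lambda g: backward(g, out))
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g: np.ndarray, out=None) -> None:
        for i, t in enumerate(tensors):
            out._acc(t, np.take(g, i, axis=axis))

    out = Tensor._make(out_data, tensors, lambda g: backward(g, out))
    return out
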