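"""Convolution primitives (im2col based) for the autodiff engine.

Layout convention: images and feature grids are NCHW.  Convolution weights
are (out_ch, in_ch, k, k); transposed-convolution weights are
(in_ch, out_ch, k, k), mirroring the common deep-learning convention so
checkpoints read naturally.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["conv2d", "conv_transpose2d", "im2col", "col2im",
           "normalize", "nchw_nhwc", "nhwc_nchw"]


def im2col(xp: np.ndarray, k: int, stride: int, ho: int, wo: int) -> np.ndarray:
    """(N,C,Hp,Wp) padded input -> (N, C*k*k, ho*wo) patch columns."""
    n, c, _, _ = xp.shape
    cols = np.empty((n, c, k, k, ho, wo), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
    return cols.reshape(n, c * k * k, ho * wo)


def col2im(cols: np.ndarray, padded_shape: tuple[int, int, int, int],
           k: int, stride: int, ho: int, wo: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add columns back onto the grid."""
    n, c, hp, wp = padded_shape
    cols = cols.reshape(n, c, k, k, ho, wo)
    x = np.zeros(padded_shape, dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            x[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += cols[:, :, i, j]
    return x


def conv2d(x: Tensor, w: Tensor, b: Tensor | None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW."""
    n, cin, h, wd = x.shape
    cout, cin_w, k, _ = w.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin_w}")
    ho = (h + 2 * padding - k) // stride + 1
    wo = (wd + 2 * padding - k) // stride + 1
    if ho < 1 or wo < 1:
        raise ValueError(f"conv2d: input {h}x{wd} too small for kernel {k}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = im2col(xp, k, stride, ho, wo)                       # (N, C*k*k, L)
    wmat = w.data.reshape(cout, cin * k * k)
    out_data = np.matmul(wmat, cols)                           # (N, cout, L)
    if b is not None:
        out_data = out_data + b.data.reshape(1, cout, 1)
    out_data = out_data.reshape(n, cout, ho, wo)

    def backward(g: np.ndarray, out=None) -> None:
        gmat = g.reshape(n, cout, ho * wo)
        if w.requires_grad:
            gw = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0)
            out._acc(w, gw.reshape(w.shape).astype(np.float32))
        if b is not None and b.requires_grad:
            out._acc(b, gmat.sum(axis=(0, 2)).astype(np.float32))
        if x.requires_grad:
            gcols = np.matmul(wmat.T, gmat)                    # (N, C*k*k, L)
            gxp = col2im(gcols, xp.shape, k, stride, ho, wo)
            if padding:
                gxp = gxp[:, :, padding:padding + h, padding:padding + wd]
            out._acc(x, gxp.astype(np.float32))

    parents = (x, w) if b is None else (x, w, b)
    out = Tensor._make(out_data.astype(np.float32), parents, lambda g: backward(g, out))
    return out


def normalize(x: Tensor, axes: tuple[int, ...], weight: Tensor | None,
              bias: Tensor | None, eps: float, param_shape) -> Tensor:
    """Fused mean/variance normalisation over ``axes`` with affine rescale.

    One primitive with an analytic backward instead of a chain of
    elementwise ops; serves both layer norm (trailing channel axis) and
    instance norm (spatial axes of NCHW grids).
    """
    mu = x.data.mean(axis=axes, keepdims=True)
    xc = x.data - mu
    var = np.mean(xc * xc, axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xn = xc * inv
    out_data = xn
    if weight is not None:
        wr = weight.data.reshape(param_shape)
        out_data = xn * wr + bias.data.reshape(param_shape)

    def backward(g: np.ndarray, out=None) -> None:
        if weight is not None:
            red = tuple(i for i in range(g.ndim) if param_shape[i] == 1)
            if weight.requires_grad:
                out._acc(weight, (g * xn).sum(axis=red).reshape(weight.shape)
                         .astype(np.float32))
            if bias.requires_grad:
                out._acc(bias, g.sum(axis=red).reshape(bias.shape)
                         .astype(np.float32))
            gxn = g * wr
        else:
            gxn = g
        if x.requires_grad:
            m1 = gxn.mean(axis=axes, keepdims=True)
            m2 = (gxn * xn).mean(axis=axes, keepdims=True)
            out._acc(x, ((gxn - m1 - xn * m2) * inv).astype(np.float32))

    parents = (x,) if weight is None else (x, weight, bias)
    out = Tensor._make(out_data.astype(np.float32), parents, lambda g: backward(g, out))
    return out


def nchw_nhwc(x: Tensor) -> Tensor:
    return x.transpose(0, 2, 3, 1)


def nhwc_nchw(x: Tensor) -> Tensor:
    return x.transpose(0, 3, 1, 2)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None,
                     stride: int = 2, padding: int = 0) -> Tensor:
    """2-D transposed convolution, NCHW; weight (in_ch, out_ch, k, k).

    Output spatial size is ``(H - 1) * stride - 2 * padding + k``.
    """
    n, cin, h, wd = x.shape
    cin_w, cout, k, _ = w.shape
    if cin != cin_w:
        raise ValueError(f"conv_transpose2d channel mismatch: input {cin}, weight {cin_w}")
    ho = (h - 1) * stride - 2 * padding + k
    wo = (wd - 1) * stride - 2 * padding + k
    hp, wp = ho + 2 * padding, wo + 2 * padding
    wmat = w.data.reshape(cin, cout * k * k)
    xmat = x.data.reshape(n, cin, h * wd)
    cols = np.matmul(wmat.T, xmat)                             # (N, cout*k*k, H*W)
    out_data = col2im(cols, (n, cout, hp, wp), k, stride, h, wd)
    if padding:
        out_data = out_data[:, :, padding:padding + ho, padding:padding + wo]
    if b is not None:
        out_data = out_data + b.data.reshape(1, cout, 1, 1)

    def backward(g: np.ndarray, out=None) -> None:
        gp = np.pad(g, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        gcols = im2col(gp, k, stride, h, wd)                   # (N, cout*k*k, H*W)
        if w.requires_grad:
            gw = np.matmul(xmat, gcols.transpose(0, 2, 1)).sum(axis=0)
            out._acc(w, gw.reshape(w.shape).astype(np.float32))
        if b is not None and b.requires_grad:
            out._acc(b, g.sum(axis=(0, 2, 3)).astype(np.float32))
        if x.requires_grad:
            gx = np.matmul(wmat, gcols)                        # (N, cin, H*W)
            out._acc(x, gx.reshape(x.shape).astype(np.float32))

    parents = (x, w) if b is None else (x, w, b)
    out = Tensor._make(out_data.astype(np.float32), parents, lambda g: backward(g, out))
    return out
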