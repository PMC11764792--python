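"""Differentiable operations used by the segmentation network.

Every function takes and returns :class:`~riceseg.nn.tensor.Tensor` and
records an exact reverse-mode gradient.  Convolution is evaluated through
strided sliding windows contracted with ``einsum`` (BLAS-backed); its input
gradient is accumulated per kernel tap, which keeps memory bounded for the
7x7 dilated kernels used by the large-kernel attention block.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .tensor import Tensor, as_tensor

__all__ = [
    "add", "mul", "div", "scale", "shift", "exp", "power", "matmul", "reshape", "transpose",
    "sum_all", "mean_all", "sum_axes", "relu", "gelu", "sigmoid", "softmax",
    "log_softmax", "layer_norm", "conv2d", "resize_bilinear", "concat",
    "narrow", "dropout", "mac_counting",
]

_MAC_COUNTER: dict | None = None


class mac_counting:
    """Context that tallies multiply-accumulate counts of traced forwards.

    Buckets: ``conv`` (all convolutions), ``linear`` (matmul against a
    trainable leaf, i.e. projection layers), ``attention`` (matmul between
    activations — the QK^T and AV products).  Elementwise work,
    normalization and interpolation are not tallied, mirroring how
    module-hook profilers see a network.
    """

    def __init__(self):
        self.macs = {"conv": 0, "linear": 0, "attention": 0}

    def __enter__(self):
        global _MAC_COUNTER
        self._prev = _MAC_COUNTER
        _MAC_COUNTER = self.macs
        return self

    def __exit__(self, *exc):
        global _MAC_COUNTER
        _MAC_COUNTER = self._prev
        return False

    @property
    def total(self) -> int:
        return sum(self.macs.values())


def _is_trainable_leaf(t: Tensor) -> bool:
    return t.requires_grad and t._backward is None and not t._parents


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# -- elementwise --------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate_grad(_unbroadcast(g, b.data.shape))

    return Tensor.result(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate_grad(_unbroadcast(g * a.data, b.data.shape))

    return Tensor.result(out_data, (a, b), backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate_grad(_unbroadcast(-g * out_data / b.data, b.data.shape))

    return Tensor.result(out_data, (a, b), backward)


def scale(a: Tensor, c: float) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(g * c)

    return Tensor.result(a.data * c, (a,), backward)


def shift(a: Tensor, c: float) -> Tensor:
    """Add a Python scalar without promoting the dtype."""

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(g)

    return Tensor.result(a.data + c, (a,), backward)


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(g * out_data)

    return Tensor.result(out_data, (a,), backward)


def power(a: Tensor, p: float) -> Tensor:
    out_data = a.data ** p

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(g * p * a.data ** (p - 1.0))

    return Tensor.result(out_data, (a,), backward)


# -- shape --------------------------------------------------------------------

def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    orig = a.data.shape

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(g.reshape(orig))

    return Tensor.result(a.data.reshape(shape), (a,), backward)


def transpose(a: Tensor, axes=None) -> Tensor:
    if axes is None:
        axes = tuple(reversed(range(a.data.ndim)))
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(g.transpose(inv))

    return Tensor.result(a.data.transpose(axes), (a,), backward)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.accumulate_grad(g[tuple(sl)])

    return Tensor.result(out_data, tuple(tensors), backward)


def narrow(a: Tensor, axis: int, start: int, length: int) -> Tensor:
    sl = [slice(None)] * a.data.ndim
    sl[axis] = slice(start, start + length)
    sl = tuple(sl)

    def backward(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            full[sl] = g
            a.accumulate_grad(full)

    return Tensor.result(a.data[sl], (a,), backward)


# -- reductions ---------------------------------------------------------------

def sum_all(a: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(np.broadcast_to(g, a.data.shape))

    return Tensor.result(a.data.sum(), (a,), backward)


def mean_all(a: Tensor) -> Tensor:
    n = a.data.size

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(np.broadcast_to(g / n, a.data.shape))

    return Tensor.result(a.data.mean(), (a,), backward)


def sum_axes(a: Tensor, axis, keepdims: bool = False) -> Tensor:
    axis = tuple(axis) if isinstance(axis, (tuple, list)) else (axis,)

    def backward(g):
        if a.requires_grad:
            if not keepdims:
                g = np.expand_dims(g, axis)
            a.accumulate_grad(np.broadcast_to(g, a.data.shape))

    return Tensor.result(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)


# -- activations --------------------------------------------------------------

def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(g * mask)

    return Tensor.result(a.data * mask, (a,), backward)


def gelu(a: Tensor) -> Tensor:
    # exact (erf) form: 0.5 x (1 + erf(x / sqrt(2)))
    from scipy.special import erf

    x = a.data
    cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
    out_data = x * cdf

    def backward(g):
        if a.requires_grad:
            pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
            a.accumulate_grad(g * (cdf + x * pdf))

    return Tensor.result(out_data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(g * out_data * (1.0 - out_data))

    return Tensor.result(out_data, (a,), backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if a.requires_grad:
            dot = (g * p).sum(axis=axis, keepdims=True)
            a.accumulate_grad(p * (g - dot))

    return Tensor.result(p, (a,), backward)


def log_softmax(a: Tensor, axis: int = -1) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out_data = z - lse

    def backward(g):
        if a.requires_grad:
            p = np.exp(out_data)
            a.accumulate_grad(g - p * g.sum(axis=axis, keepdims=True))

    return Tensor.result(out_data, (a,), backward)


# -- matmul -------------------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data
    if _MAC_COUNTER is not None:
        bucket = "linear" if (_is_trainable_leaf(a) or _is_trainable_leaf(b)) else "attention"
        _MAC_COUNTER[bucket] += int(np.prod(out_data.shape, dtype=np.int64)) * a.data.shape[-1]

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a.accumulate_grad(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b.accumulate_grad(_unbroadcast(gb, b.data.shape))

    return Tensor.result(out_data, (a, b), backward)


# -- normalization ------------------------------------------------------------

def layer_norm(x: Tensor, weight: Tensor, bias: Tensor, eps: float = 1e-6) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * weight.data + bias.data
    n = x.data.shape[-1]

    def backward(g):
        if bias.requires_grad:
            bias.accumulate_grad(g.reshape(-1, n).sum(axis=0))
        if weight.requires_grad:
            weight.accumulate_grad((g * xhat).reshape(-1, n).sum(axis=0))
        if x.requires_grad:
            gh = g * weight.data
            term = gh - gh.mean(axis=-1, keepdims=True) - xhat * (gh * xhat).mean(axis=-1, keepdims=True)
            x.accumulate_grad(term * inv)

    return Tensor.result(out_data, (x, weight, bias), backward)


# -- convolution --------------------------------------------------------------

def _conv_out_size(n: int, k: int, s: int, p: int, d: int) -> int:
    eff = d * (k - 1) + 1
    return (n + 2 * p - eff) // s + 1


def _windows(xp: np.ndarray, kh: int, kw: int, s: int, d: int, ho: int, wo: int):
    b, c, _, _ = xp.shape
    sb, sc, sh, sw = xp.strides
    shape = (b, c, ho, wo, kh, kw)
    strides = (sb, sc, s * sh, s * sw, d * sh, d * sw)
    return as_strided(xp, shape=shape, strides=strides, writeable=False)


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
    groups: int = 1,
) -> Tensor:
    """2-D cross-correlation on NCHW input.

    ``weight`` has shape ``(C_out, C_in/groups, kh, kw)``.  Depthwise
    convolution (``groups == C_in`` with multiplier 1) takes a dedicated
    contraction path; other group counts fall back to a per-group loop.
    """
    b, cin, h, w = x.data.shape
    cout, cin_g, kh, kw = weight.data.shape
    if cin_g * groups != cin:
        raise ValueError(f"weight expects {cin_g * groups} input channels, got {cin}")
    ho = _conv_out_size(h, kh, stride, padding, dilation)
    wo = _conv_out_size(w, kw, stride, padding, dilation)
    if ho <= 0 or wo <= 0:
        raise ValueError(f"input {h}x{w} too small for kernel {kh}x{kw} (dilation {dilation})")
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = x.data
    win = _windows(xp, kh, kw, stride, dilation, ho, wo)

    depthwise = groups == cin and cout == cin
    if depthwise:
        out_data = np.einsum("bcijkl,ckl->bcij", win, weight.data[:, 0], optimize=True)
    elif groups == 1:
        out_data = np.einsum("bcijkl,ockl->boij", win, weight.data, optimize=True)
    else:
        chunks = []
        for gidx in range(groups):
            wslice = weight.data[gidx * (cout // groups):(gidx + 1) * (cout // groups)]
            wchunk = win[:, gidx * cin_g:(gidx + 1) * cin_g]
            chunks.append(np.einsum("bcijkl,ockl->boij", wchunk, wslice, optimize=True))
        out_data = np.concatenate(chunks, axis=1)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]
    if _MAC_COUNTER is not None:
        _MAC_COUNTER["conv"] += b * cout * cin_g * kh * kw * ho * wo

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias.accumulate_grad(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            if depthwise:
                gw = np.einsum("bcijkl,bcij->ckl", win, g, optimize=True)[:, None]
            elif groups == 1:
                gw = np.einsum("bcijkl,boij->ockl", win, g, optimize=True)
            else:
                parts = []
                for gidx in range(groups):
                    gchunk = g[:, gidx * (cout // groups):(gidx + 1) * (cout // groups)]
                    wchunk = win[:, gidx * cin_g:(gidx + 1) * cin_g]
                    parts.append(np.einsum("bcijkl,boij->ockl", wchunk, gchunk, optimize=True))
                gw = np.concatenate(parts, axis=0)
            weight.accumulate_grad(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    if depthwise:
                        contrib = g * weight.data[:, 0, i, j][None, :, None, None]
                    elif groups == 1:
                        contrib = np.einsum("boij,oc->bcij", g, weight.data[:, :, i, j], optimize=True)
                    else:
                        parts = []
                        for gidx in range(groups):
                            gchunk = g[:, gidx * (cout // groups):(gidx + 1) * (cout // groups)]
                            wtap = weight.data[gidx * (cout // groups):(gidx + 1) * (cout // groups), :, i, j]
                            parts.append(np.einsum("boij,oc->bcij", gchunk, wtap, optimize=True))
                        contrib = np.concatenate(parts, axis=1)
                    gxp[:, :, i * dilation:i * dilation + ho * stride:stride,
                        j * dilation:j * dilation + wo * stride:stride] += contrib
            if padding:
                gxp = gxp[:, :, padding:padding + h, padding:padding + w]
            x.accumulate_grad(gxp)

    return Tensor.result(out_data, parents, backward)


# -- resampling ---------------------------------------------------------------

def resize_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize (align_corners=False), NCHW."""
    b, c, h, w = x.data.shape
    if (out_h, out_w) == (h, w):
        return x
    ys = (np.arange(out_h) + 0.5) * (h / out_h) - 0.5
    xs = (np.arange(out_w) + 0.5) * (w / out_w) - 0.5
    y0 = np.clip(np.floor(ys).astype(np.int64), 0, h - 1)
    x0 = np.clip(np.floor(xs).astype(np.int64), 0, w - 1)
    y1 = np.clip(y0 + 1, 0, h - 1)
    x1 = np.clip(x0 + 1, 0, w - 1)
    wy = np.clip(ys - np.floor(ys), 0.0, 1.0)
    wx = np.clip(xs - np.floor(xs), 0.0, 1.0)
    wy = np.where(ys < 0, 0.0, wy)
    wx = np.where(xs < 0, 0.0, wx)

    w00 = ((1 - wy)[:, None] * (1 - wx)[None, :]).astype(x.data.dtype)
    w01 = ((1 - wy)[:, None] * wx[None, :]).astype(x.data.dtype)
    w10 = (wy[:, None] * (1 - wx)[None, :]).astype(x.data.dtype)
    w11 = (wy[:, None] * wx[None, :]).astype(x.data.dtype)

    out_data = (
        x.data[:, :, y0[:, None], x0[None, :]] * w00
        + x.data[:, :, y0[:, None], x1[None, :]] * w01
        + x.data[:, :, y1[:, None], x0[None, :]] * w10
        + x.data[:, :, y1[:, None], x1[None, :]] * w11
    )

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            flat = gx.reshape(b, c, -1)
            for yy, xx, ww in ((y0, x0, w00), (y0, x1, w01), (y1, x0, w10), (y1, x1, w11)):
                idx = (yy[:, None] * w + xx[None, :]).ravel()
                np.add.at(flat, (slice(None), slice(None), idx), (g * ww).reshape(b, c, -1))
            x.accumulate_grad(gx)

    return Tensor.result(out_data, (x,), backward)


# -- regularization -----------------------------------------------------------

def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = 1.0 - p
    mask = (rng.random(x.data.shape) < keep).astype(x.data.dtype) / keep

    def backward(g):
        if x.requires_grad:
            x.accumulate_grad(g * mask)

    return Tensor.result(x.data * mask, (x,), backward)
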