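"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float32 ndarray and records the operations that
produced it; :meth:`Tensor.backward` walks the tape in reverse topological
order and accumulates gradients.  Only the primitives needed by a 2D
convolutional encoder-decoder are provided: broadcasting arithmetic,
matmul, pointwise nonlinearities, reductions, concatenation, 2D
convolution (im2col + GEMM), max pooling, and separable bilinear
resampling expressed as two constant interpolation matrices.

The engine is single-device, eager, and deterministic: identical inputs
produce bit-identical outputs and gradients.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "add", "mul", "matmul", "relu", "sigmoid", "log", "exp", "clip",
    "tsum", "tmean", "tmax", "concat", "reshape",
    "conv2d", "maxpool2d", "interp2d", "bilinear_matrix",
]

_DTYPE = np.float32


class Tensor:
    """An ndarray with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._prev = ()

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------
    def backward(self, grad=None):
        """Accumulate gradients of ``self`` w.r.t. every upstream tensor."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=_DTYPE)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        return mul(self, power(as_tensor(other), -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def max(self, axis=None, keepdims=False):
        return tmax(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._prev = tuple(parents)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray):
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.astype(_DTYPE, copy=False)
    else:
        t.grad = t.grad + g


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum-reduce ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _node(out_data, (a, b), backward)


def power(a, p) -> Tensor:
    a = as_tensor(a)
    p = float(p)
    out_data = a.data ** p

    def backward(g):
        _accum(a, g * p * a.data ** (p - 1.0))

    return _node(out_data, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        _accum(a, _unbroadcast(ga, a.data.shape))
        _accum(b, _unbroadcast(gb, b.data.shape))

    return _node(out_data, (a, b), backward)


# ---------------------------------------------------------------------
# pointwise
# ---------------------------------------------------------------------

def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    out_data = a.data * mask

    def backward(g):
        _accum(a, g * mask)

    return _node(out_data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    # numerically stable logistic, kept strictly inside (0, 1) so the
    # open-interval contract survives float32 saturation
    s = np.empty_like(a.data)
    pos = a.data >= 0
    s[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    ez = np.exp(a.data[~pos])
    s[~pos] = ez / (1.0 + ez)
    s = np.clip(s, 1e-7, 1.0 - 1e-7)

    def backward(g):
        _accum(a, g * s * (1.0 - s))

    return _node(s, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.log(a.data)

    def backward(g):
        _accum(a, g / a.data)

    return _node(out_data, (a,), backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        _accum(a, g * out_data)

    return _node(out_data, (a,), backward)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp to [lo, hi]; gradient passes only where unclamped."""
    a = as_tensor(a)
    out_data = np.clip(a.data, lo, hi)
    mask = (a.data >= lo) & (a.data <= hi)

    def backward(g):
        _accum(a, g * mask)

    return _node(out_data, (a,), backward)


# ---------------------------------------------------------------------
# reductions / shape
# ---------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g, a.data.shape).astype(_DTYPE))

    return _node(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.mean(axis=axis, keepdims=keepdims)
    n = a.data.size / max(out_data.size, 1)

    def backward(g):
        g = np.asarray(g) / n
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g, a.data.shape).astype(_DTYPE))

    return _node(out_data, (a,), backward)


def tmax(a, axis=None, keepdims=False) -> Tensor:
    """Max reduction; ties share the gradient equally (deterministic)."""
    a = as_tensor(a)
    out_data = a.data.max(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        full = out_data
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
            full = np.expand_dims(out_data, axis)
        mask = (a.data == full)
        counts = mask.sum(axis=axis, keepdims=True) if axis is not None else mask.sum()
        _accum(a, (mask * (g / counts)).astype(_DTYPE))

    return _node(out_data, (a,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return _node(out_data, tuple(tensors), backward)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        _accum(a, g.reshape(a.data.shape))

    return _node(out_data, (a,), backward)


# ---------------------------------------------------------------------
# spatial ops
# ---------------------------------------------------------------------

def conv2d(x, w, b=None, stride: int = 1, padding: int = 0) -> Tensor:
    """2D cross-correlation of NCHW input with OIHW weights."""
    x, w = as_tensor(x), as_tensor(w)
    N, C, H, W = x.data.shape
    O, Ci, kh, kw = w.data.shape
    if Ci != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Ci}")
    s, p = int(stride), int(padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    # (N, C, Ho, Wo, kh, kw) -> (N*Ho*Wo, C*kh*kw)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N * Ho * Wo, C * kh * kw)
    wm = w.data.reshape(O, -1)
    out = cols @ wm.T
    if b is not None:
        b = as_tensor(b)
        out = out + b.data
    out_data = out.reshape(N, Ho, Wo, O).transpose(0, 3, 1, 2)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * Ho * Wo, O)
        if b is not None:
            _accum(b, gm.sum(axis=0))
        _accum(w, (gm.T @ cols).reshape(w.data.shape))
        if x.requires_grad:
            dcols = gm @ wm  # (N*Ho*Wo, C*kh*kw)
            dwin = dcols.reshape(N, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += dwin[:, :, :, :, i, j]
            _accum(x, dxp[:, :, p:p + H, p:p + W] if p else dxp)

    return _node(out_data, parents, backward)


def maxpool2d(x, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    x = as_tensor(x)
    N, C, H, W = x.data.shape
    k, s, p = int(kernel), int(stride), int(padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)),
                constant_values=-np.inf) if p else x.data
    Ho = (H + 2 * p - k) // s + 1
    Wo = (W + 2 * p - k) // s + 1
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    out_data = win.max(axis=(-2, -1))

    def backward(g):
        mask = (win == out_data[..., None, None])
        counts = mask.sum(axis=(-2, -1), keepdims=True)
        dwin = mask * (g[..., None, None] / counts)
        dxp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=_DTYPE)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += dwin[..., i, j]
        _accum(x, dxp[:, :, p:p + H, p:p + W] if p else dxp)

    return _node(out_data, (x,), backward)


def bilinear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic 1D bilinear interpolation matrix (half-pixel centers).

    ``A @ v`` resamples a length ``n_in`` signal to length ``n_out``; 2D
    bilinear resampling is the separable product ``A_h @ X @ A_w.T``.
    """
    A = np.zeros((n_out, n_in), dtype=_DTYPE)
    if n_in == 1:
        A[:, 0] = 1.0
        return A
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    f = (src - i0).astype(_DTYPE)
    rows = np.arange(n_out)
    np.add.at(A, (rows, i0), 1.0 - f)
    np.add.at(A, (rows, i1), f)
    return A


def interp2d(x, Ah: np.ndarray, Aw: np.ndarray) -> Tensor:
    """Separable linear resampling of NCHW input: ``Ah @ x @ Aw.T``."""
    x = as_tensor(x)
    out_data = np.matmul(np.matmul(Ah, x.data), Aw.T)

    def backward(g):
        _accum(x, np.matmul(np.matmul(Ah.T, g), Aw).astype(_DTYPE))

    return _node(out_data, (x,), backward)
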