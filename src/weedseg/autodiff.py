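"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine is deliberately small: a :class:`Tensor` wraps an ``ndarray``,
operations build a tape of backward closures, and :meth:`Tensor.backward`
walks the tape in reverse topological order.  Only the primitives needed by
the segmentation network are provided (elementwise math, reductions,
2-D convolution, depthwise convolution, bilinear resampling, matmul,
layer normalization).

Convolution and matmul primitives also report multiply-accumulate counts to
an active :class:`mac_counter`, so one forward pass doubles as an exact
per-layer operation count.
"""

from __future__ import annotations

import contextlib
from functools import lru_cache

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

__all__ = [
    "Tensor",
    "as_tensor",
    "no_grad",
    "mac_counter",
    "concat",
    "channel_slice",
    "conv2d",
    "depthwise_conv2d",
    "bilinear_resize",
    "linear",
    "layer_norm",
]

_GRAD_ENABLED = [True]
_MAC_STACK: list["mac_counter"] = []


@contextlib.contextmanager
def no_grad():
    """Disable tape recording (saves memory during inference/counting)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


class mac_counter:
    """Context manager accumulating multiply-accumulate counts of conv/linear ops."""

    def __init__(self) -> None:
        self.total = 0

    def __enter__(self) -> "mac_counter":
        _MAC_STACK.append(self)
        return self

    def __exit__(self, *exc) -> None:
        _MAC_STACK.remove(self)


def _add_macs(n: int) -> None:
    for c in _MAC_STACK:
        c.total += int(n)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverses NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64 if np.asarray(data).dtype == np.float64 else np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- infrastructure -----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar Tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # release the tape eagerly: backward closures capture large buffers
        # (im2col matrices) and form reference cycles with their outputs
        for node in topo:
            node._backward = None
            node._parents = ()
            if not node.requires_grad:
                node.grad = None

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out._parents:
            def bwd(g, a=self, b=other, out=out):
                if a.requires_grad or a._parents:
                    a._accum(_unbroadcast(g, a.data.shape))
                if b.requires_grad or b._parents:
                    b._accum(_unbroadcast(g, b.data.shape))
            out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out._parents:
            out._backward = lambda g, a=self: a._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out._parents:
            def bwd(g, a=self, b=other):
                if a.requires_grad or a._parents:
                    a._accum(_unbroadcast(g * b.data, a.data.shape))
                if b.requires_grad or b._parents:
                    b._accum(_unbroadcast(g * a.data, b.data.shape))
            out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = _make(self.data / other.data, (self, other))
        if out._parents:
            def bwd(g, a=self, b=other):
                if a.requires_grad or a._parents:
                    a._accum(_unbroadcast(g / b.data, a.data.shape))
                if b.requires_grad or b._parents:
                    b._accum(_unbroadcast(-g * a.data / b.data**2, b.data.shape))
            out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = _make(self.data ** exponent, (self,))
        if out._parents:
            def bwd(g, a=self, e=exponent, y=out.data):
                a._accum(g * e * a.data ** (e - 1.0))
            out._backward = bwd
        return out

    # -- elementwise nonlinearities ----------------------------------------

    def relu(self):
        out = _make(np.maximum(self.data, 0.0), (self,))
        if out._parents:
            out._backward = lambda g, a=self: a._accum(g * (a.data > 0))
        return out

    def sigmoid(self):
        x = self.data
        s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                     np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        out = _make(s.astype(x.dtype), (self,))
        if out._parents:
            out._backward = lambda g, a=self, s=out.data: a._accum(g * s * (1.0 - s))
        return out

    def gelu(self):
        x = self.data
        phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out = _make((x * phi).astype(x.dtype), (self,))
        if out._parents:
            def bwd(g, a=self, phi=phi):
                x = a.data
                pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
                a._accum(g * (phi + x * pdf))
            out._backward = bwd
        return out

    def exp(self):
        out = _make(np.exp(self.data), (self,))
        if out._parents:
            out._backward = lambda g, a=self, y=out.data: a._accum(g * y)
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out._parents:
            out._backward = lambda g, a=self: a._accum(g / a.data)
        return out

    def clip(self, lo: float, hi: float):
        out = _make(np.clip(self.data, lo, hi), (self,))
        if out._parents:
            def bwd(g, a=self, lo=lo, hi=hi):
                inside = (a.data >= lo) & (a.data <= hi)
                a._accum(g * inside)
            out._backward = bwd
        return out

    # -- reductions / shape -------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out._parents:
            def bwd(g, a=self, axis=axis, keepdims=keepdims):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g, a.data.shape).astype(a.data.dtype))
            out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out._parents:
            out._backward = lambda g, a=self: a._accum(g.reshape(a.data.shape))
        return out

    def transpose(self, axes):
        out = _make(self.data.transpose(axes), (self,))
        if out._parents:
            inv = np.argsort(axes)
            out._backward = lambda g, a=self, inv=tuple(inv): a._accum(g.transpose(inv))
        return out


def _make(data: np.ndarray, parents: tuple) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED[-1] and any(p.requires_grad or p._parents for p in parents):
        out._parents = parents
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out._parents:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def bwd(g, ts=tensors, splits=splits, axis=axis):
            for t, piece in zip(ts, np.split(g, splits, axis=axis)):
                if t.requires_grad or t._parents:
                    t._accum(piece)
        out._backward = bwd
    return out


def channel_slice(x: Tensor, start: int, stop: int) -> Tensor:
    """Slice channels (axis 1) of an NCHW tensor, differentiably."""
    out = _make(x.data[:, start:stop], (x,))
    if out._parents:
        def bwd(g, x=x, start=start, stop=stop):
            gx = np.zeros_like(x.data)
            gx[:, start:stop] = g
            x._accum(gx)
        out._backward = bwd
    return out


# -- dense / convolution primitives ----------------------------------------


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """``x @ w (+ b)`` with ``w`` of shape (in, out); leading dims of x are batch."""
    xd, wd = x.data, w.data
    out_data = xd @ wd
    if b is not None:
        out_data = out_data + b.data
    _add_macs(int(np.prod(xd.shape[:-1])) * wd.shape[0] * wd.shape[1])
    parents = (x, w) if b is None else (x, w, b)
    out = _make(out_data, parents)
    if out._parents:
        def bwd(g, x=x, w=w, b=b):
            if x.requires_grad or x._parents:
                x._accum(g @ w.data.T)
            if w.requires_grad or w._parents:
                gm = g.reshape(-1, g.shape[-1])
                xm = x.data.reshape(-1, x.data.shape[-1])
                w._accum(xm.T @ gm)
            if b is not None and (b.requires_grad or b._parents):
                b._accum(g.reshape(-1, g.shape[-1]).sum(axis=0))
        out._backward = bwd
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW input, OIHW weights."""
    xd, wd = x.data, w.data
    n, c, h, wid = xd.shape
    co, ci, kh, kw = wd.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input {c}, weight expects {ci}")
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = (xd.shape[2] - kh) // stride + 1
    wo = (xd.shape[3] - kw) // stride + 1
    win = sliding_window_view(xd, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    out_mat = cols @ wd.reshape(co, -1).T
    if b is not None:
        out_mat = out_mat + b.data
    _add_macs(n * ho * wo * co * c * kh * kw)
    out_data = out_mat.reshape(n, ho, wo, co).transpose(0, 3, 1, 2)
    parents = (x, w) if b is None else (x, w, b)
    out = _make(np.ascontiguousarray(out_data), parents)
    if out._parents:
        def bwd(g, x=x, w=w, b=b, cols=cols, dims=(n, c, h, wid, ho, wo, kh, kw, stride, padding)):
            n, c, h, wid, ho, wo, kh, kw, stride, padding = dims
            co = w.data.shape[0]
            gm = g.transpose(0, 2, 3, 1).reshape(-1, co)
            if w.requires_grad or w._parents:
                w._accum((gm.T @ cols).reshape(w.data.shape))
            if b is not None and (b.requires_grad or b._parents):
                b._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad or x._parents:
                gcols = (gm @ w.data.reshape(co, -1)).reshape(n, ho, wo, c, kh, kw)
                gx = np.zeros((n, c, h + 2 * padding, wid + 2 * padding), dtype=x.data.dtype)
                for i in range(kh):
                    for j in range(kw):
                        gx[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                            gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                if padding:
                    gx = gx[:, :, padding:padding + h, padding:padding + wid]
                x._accum(gx)
        out._backward = bwd
    return out


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     padding: int = 0) -> Tensor:
    """Depthwise convolution, stride 1; weights of shape (C, kh, kw)."""
    xd, wd = x.data, w.data
    n, c, h, wid = xd.shape
    cw, kh, kw = wd.shape
    if cw != c:
        raise ValueError("depthwise weight channel mismatch")
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = xd.shape[2] - kh + 1
    wo = xd.shape[3] - kw + 1
    win = sliding_window_view(xd, (kh, kw), axis=(2, 3))
    out_data = np.einsum("nchwij,cij->nchw", win, wd, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    _add_macs(n * c * ho * wo * kh * kw)
    parents = (x, w) if b is None else (x, w, b)
    out = _make(out_data, parents)
    if out._parents:
        def bwd(g, x=x, w=w, b=b, win=win, dims=(n, c, h, wid, ho, wo, kh, kw, padding)):
            n, c, h, wid, ho, wo, kh, kw, padding = dims
            if w.requires_grad or w._parents:
                w._accum(np.einsum("nchw,nchwij->cij", g, win, optimize=True))
            if b is not None and (b.requires_grad or b._parents):
                b._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad or x._parents:
                gx = np.zeros((n, c, h + 2 * padding, wid + 2 * padding), dtype=x.data.dtype)
                for i in range(kh):
                    for j in range(kw):
                        gx[:, :, i:i + ho, j:j + wo] += g * w.data[None, :, i, j, None, None]
                if padding:
                    gx = gx[:, :, padding:padding + h, padding:padding + wid]
                x._accum(gx)
        out._backward = bwd
    return out


@lru_cache(maxsize=64)
def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """1-D linear interpolation matrix with half-pixel-center sampling."""
    m = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    src = np.clip((np.arange(n_out) + 0.5) * scale - 0.5, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    frac = (src - i0).astype(np.float32)
    np.add.at(m, (np.arange(n_out), i0), 1.0 - frac)
    np.add.at(m, (np.arange(n_out), i1), frac)
    return m


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Bilinear resampling of an NCHW tensor to (out_h, out_w)."""
    oh, ow = out_hw
    n, c, h, w = x.data.shape
    if (oh, ow) == (h, w):
        return x
    lh = _interp_matrix(oh, h)
    lw = _interp_matrix(ow, w)
    t = x.data @ lw.T                       # (n, c, h, ow)
    out_data = np.einsum("oh,nchw->ncow", lh, t, optimize=True)
    out = _make(out_data, (x,))
    if out._parents:
        def bwd(g, x=x, lh=lh, lw=lw):
            t = np.einsum("oh,ncow->nchw", lh, g, optimize=True)  # lh^T applied on rows
            x._accum(t @ lw)
        out._backward = bwd
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, axis: int = 1,
               eps: float = 1e-6) -> Tensor:
    """Layer normalization over a single axis; gamma/beta broadcast on that axis."""
    xd = x.data
    mu = xd.mean(axis=axis, keepdims=True)
    var = xd.var(axis=axis, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu) * inv
    shape = [1] * xd.ndim
    shape[axis] = xd.shape[axis]
    gd = gamma.data.reshape(shape)
    bd = beta.data.reshape(shape)
    out = _make(xhat * gd + bd, (x, gamma, beta))
    if out._parents:
        def bwd(g, x=x, gamma=gamma, beta=beta, xhat=xhat, inv=inv, gd=gd,
                axis=axis, shape=tuple(shape)):
            if gamma.requires_grad or gamma._parents:
                red = tuple(i for i in range(g.ndim) if i != axis)
                gamma._accum((g * xhat).sum(axis=red))
            if beta.requires_grad or beta._parents:
                red = tuple(i for i in range(g.ndim) if i != axis)
                beta._accum(g.sum(axis=red))
            if x.requires_grad or x._parents:
                gh = g * gd
                m1 = gh.mean(axis=axis, keepdims=True)
                m2 = (gh * xhat).mean(axis=axis, keepdims=True)
                x._accum(inv * (gh - m1 - xhat * m2))
        out._backward = bwd
    return out
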