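"""Minimal reverse-mode automatic differentiation over numpy arrays.

The networks in this package are small (tens of thousands of parameters,
desk-scale images), so a compact tape-based engine is sufficient: each
:class:`Tensor` records its parents and a closure that propagates the
upstream gradient. Only the operations the MTL/MIL models need are
implemented — elementwise arithmetic, matmul, reductions, softmax,
strided 2-d convolution, 2x2/stride-2 transposed convolution, area
average pooling and bilinear upsampling.

Gradients are accumulated in ``float64`` (the engine keeps all data in
float64); every op is covered by finite-difference checks in the test
suite.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- graph construction ----------------------------------------------

    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward(out)
        return out

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)

        def bw(out):
            def fn(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g, self.data.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g, other.data.shape))
            return fn

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(out):
            def fn(g):
                if self.requires_grad:
                    self._accumulate(-g)
            return fn

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bw(out):
            def fn(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g * other.data, self.data.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g * self.data, other.data.shape))
            return fn

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def bw(out):
            def fn(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g / other.data, self.data.shape))
                if other.requires_grad:
                    other._accumulate(
                        _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                    )
            return fn

        return Tensor._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")

        def bw(out):
            def fn(g):
                if self.requires_grad:
                    self._accumulate(g * p * self.data ** (p - 1))
            return fn

        return Tensor._make(self.data**p, (self,), bw)

    def __matmul__(self, other):
        other = as_tensor(other)

        def bw(out):
            def fn(g):
                if self.requires_grad:
                    ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                    self._accumulate(_unbroadcast(ga, self.data.shape))
                if other.requires_grad:
                    gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                    other._accumulate(_unbroadcast(gb, other.data.shape))
            return fn

        return Tensor._make(np.matmul(self.data, other.data), (self, other), bw)

    def __getitem__(self, idx):
        def bw(out):
            def fn(g):
                if self.requires_grad:
                    gx = np.zeros_like(self.data)
                    np.add.at(gx, idx, g)
                    self._accumulate(gx)
            return fn

        return Tensor._make(self.data[idx], (self,), bw)

    # -- reductions / shape ----------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def bw(out):
            def fn(g):
                if not self.requires_grad:
                    return
                if axis is None:
                    self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                    return
                gg = g
                if not keepdims:
                    gg = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())
            return fn

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bw(out):
            def fn(g):
                if self.requires_grad:
                    self._accumulate(g.reshape(old))
            return fn

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(out):
            def fn(g):
                if self.requires_grad:
                    self._accumulate(g.transpose(inv))
            return fn

        return Tensor._make(self.data.transpose(axes), (self,), bw)

    # -- nonlinearities ---------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def bw(out):
            def fn(g):
                if self.requires_grad:
                    self._accumulate(g * mask)
            return fn

        return Tensor._make(self.data * mask, (self,), bw)

    def sigmoid(self):
        x = self.data
        y = np.empty_like(x)
        pos = x >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        y[~pos] = ex / (1.0 + ex)

        def bw(out):
            def fn(g):
                if self.requires_grad:
                    self._accumulate(g * y * (1.0 - y))
            return fn

        return Tensor._make(y, (self,), bw)

    def exp(self):
        y = np.exp(self.data)

        def bw(out):
            def fn(g):
                if self.requires_grad:
                    self._accumulate(g * y)
            return fn

        return Tensor._make(y, (self,), bw)

    def log(self):
        def bw(out):
            def fn(g):
                if self.requires_grad:
                    self._accumulate(g / self.data)
            return fn

        return Tensor._make(np.log(self.data), (self,), bw)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through unclamped entries."""
        inside = (self.data >= lo) & (self.data <= hi)

        def bw(out):
            def fn(g):
                if self.requires_grad:
                    self._accumulate(g * inside)
            return fn

        return Tensor._make(np.clip(self.data, lo, hi), (self,), bw)

    def softmax(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)
        e = np.exp(self.data - m)
        y = e / e.sum(axis=axis, keepdims=True)

        def bw(out):
            def fn(g):
                if self.requires_grad:
                    dot = (g * y).sum(axis=axis, keepdims=True)
                    self._accumulate(y * (g - dot))
            return fn

        return Tensor._make(y, (self,), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bw(out):
        def fn(g):
            for t, a, b in zip(ts, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(a, b)
                    t._accumulate(g[tuple(sl)])
        return fn

    return Tensor._make(np.concatenate([t.data for t in ts], axis=axis), ts, bw)


# -- spatial ops (NCHW layout) -------------------------------------------


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """Strided 2-d cross-correlation: x [N,Ci,H,W], w [Co,Ci,kh,kw]."""
    s, p = stride, padding
    kh, kw = w.data.shape[2:]
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    y = np.einsum("nchwkl,ockl->nohw", win, w.data, optimize=True)
    if b is not None:
        y = y + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def bw(out):
        def fn(g):
            if w.requires_grad:
                w._accumulate(np.einsum("nchwkl,nohw->ockl", win, g, optimize=True))
            if b is not None and b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                ho, wo = g.shape[2:]
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        contrib = np.einsum("nohw,oc->nchw", g, w.data[:, :, i, j],
                                            optimize=True)
                        gxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += contrib
                if p:
                    gxp = gxp[:, :, p:-p, p:-p]
                x._accumulate(gxp)
        return fn

    return Tensor._make(y, parents, bw)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution with kernel 2, stride 2 (exact 2x upscale).

    x [N,Ci,h,w], w [Ci,Co,2,2] -> y [N,Co,2h,2w]. Output blocks are
    disjoint, so forward/backward reduce to einsum + reshape.
    """
    n, ci, h, wd = x.data.shape
    co = w.data.shape[1]
    t = np.einsum("nchw,codk->nohdwk", x.data, w.data, optimize=True)
    y = t.reshape(n, co, 2 * h, 2 * wd)
    if b is not None:
        y = y + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def bw(out):
        def fn(g):
            gr = g.reshape(n, co, h, 2, wd, 2)
            if x.requires_grad:
                x._accumulate(np.einsum("nohdwk,codk->nchw", gr, w.data, optimize=True))
            if w.requires_grad:
                w._accumulate(np.einsum("nchw,nohdwk->codk", x.data, gr, optimize=True))
            if b is not None and b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2, 3)))
        return fn

    return Tensor._make(y, parents, bw)


def avg_pool_to(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Area-average pooling to an exact divisor resolution."""
    n, c, h, w = x.data.shape
    ho, wo = size
    if h % ho or w % wo:
        raise ValueError(f"cannot area-pool {h}x{w} to {ho}x{wo}")
    fh, fw = h // ho, w // wo
    y = x.data.reshape(n, c, ho, fh, wo, fw).mean(axis=(3, 5))

    def bw(out):
        def fn(g):
            if x.requires_grad:
                gx = np.broadcast_to(
                    g[:, :, :, None, :, None], (n, c, ho, fh, wo, fw)
                ) / (fh * fw)
                x._accumulate(gx.reshape(n, c, h, w))
        return fn

    return Tensor._make(y, (x,), bw)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Half-pixel-aligned 1-d bilinear interpolation matrix [n_out, n_in]."""
    a = np.zeros((n_out, n_in))
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    f = src - i0
    np.add.at(a, (np.arange(n_out), i0), 1 - f)
    np.add.at(a, (np.arange(n_out), i1), f)
    return a


def upsample_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Bilinear upsampling of x [N,C,h,w] to `size` (half-pixel centers)."""
    n, c, h, w = x.data.shape
    ho, wo = size
    a = _interp_matrix(ho, h)
    bmat = _interp_matrix(wo, w)
    y = np.einsum("oh,nchw,pw->ncop", a, x.data, bmat, optimize=True)

    def bw(out):
        def fn(g):
            if x.requires_grad:
                x._accumulate(np.einsum("oh,ncop,pw->nchw", a, g, bmat, optimize=True))
        return fn

    return Tensor._make(y, (x,), bw)
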