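"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A deliberately small engine — just the operations the denoising and
segmentation networks need: stride-1 2D convolution, max pooling, nearest
upsampling, channel concatenation, elementwise nonlinearities and
reductions.  All convolution arithmetic runs through im2col views and
``np.tensordot``, so the heavy lifting stays inside BLAS.

Tensors carry ``(N, C, H, W)`` activations or arbitrary-shape parameters.
Gradients are accumulated into ``.grad`` by :meth:`Tensor.backward`
(topological order, standard vector-Jacobian products).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "add", "sub", "mul", "div", "neg", "power",
    "relu", "sigmoid", "exp", "log", "sqrt",
    "tsum", "tmean",
    "conv2d", "maxpool2d", "upsample_nearest", "concat",
    "global_avg_pool", "reshape",
]


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _vjp=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._vjp = _vjp  # callable(grad_out) -> tuple of parent grads

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # operator sugar ------------------------------------------------------
    def __add__(self, other): return add(self, other)
    __radd__ = __add__
    def __sub__(self, other): return sub(self, other)
    def __rsub__(self, other): return sub(other, self)
    def __mul__(self, other): return mul(self, other)
    __rmul__ = __mul__
    def __truediv__(self, other): return div(self, other)
    def __rtruediv__(self, other): return div(other, self)
    def __neg__(self): return neg(self)
    def __pow__(self, p): return power(self, p)

    def sum(self, axis=None, keepdims=False): return tsum(self, axis, keepdims)
    def mean(self, axis=None, keepdims=False): return tmean(self, axis, keepdims)

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._vjp is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._vjp(node.grad)):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g

    def zero_grad(self) -> None:
        self.grad = None


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum grad down to `shape` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


# --------------------------------------------------------------------------
# elementwise / broadcasting ops
# --------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data + b.data, _parents=(a, b),
                 _vjp=lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))
    return out


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(a.data - b.data, _parents=(a, b),
                  _vjp=lambda g: (_unbroadcast(g, a.shape), _unbroadcast(-g, b.shape)))


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(a.data * b.data, _parents=(a, b),
                  _vjp=lambda g: (_unbroadcast(g * b.data, a.shape),
                                  _unbroadcast(g * a.data, b.shape)))


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(a.data / b.data, _parents=(a, b),
                  _vjp=lambda g: (_unbroadcast(g / b.data, a.shape),
                                  _unbroadcast(-g * a.data / b.data ** 2, b.shape)))


def neg(a) -> Tensor:
    a = as_tensor(a)
    return Tensor(-a.data, _parents=(a,), _vjp=lambda g: (-g,))


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    return Tensor(a.data ** p, _parents=(a,),
                  _vjp=lambda g: (g * p * a.data ** (p - 1),))


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    return Tensor(a.data * mask, _parents=(a,), _vjp=lambda g: (g * mask,))


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))
    return Tensor(s, _parents=(a,), _vjp=lambda g: (g * s * (1 - s),))


def exp(a) -> Tensor:
    a = as_tensor(a)
    e = np.exp(a.data)
    return Tensor(e, _parents=(a,), _vjp=lambda g: (g * e,))


def log(a) -> Tensor:
    a = as_tensor(a)
    return Tensor(np.log(a.data), _parents=(a,), _vjp=lambda g: (g / a.data,))


def sqrt(a) -> Tensor:
    a = as_tensor(a)
    r = np.sqrt(a.data)
    return Tensor(r, _parents=(a,), _vjp=lambda g: (g * 0.5 / r,))


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return (np.broadcast_to(g, a.shape).copy(),)
        gg = g
        if not keepdims:
            gg = np.expand_dims(g, axis)
        return (np.broadcast_to(gg, a.shape).copy(),)

    return Tensor(out, _parents=(a,), _vjp=vjp)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return tsum(a, axis, keepdims) * (1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    return Tensor(a.data.reshape(shape), _parents=(a,),
                  _vjp=lambda g: (g.reshape(a.shape),))


# --------------------------------------------------------------------------
# convolution / pooling / resampling (NCHW, stride 1)
# --------------------------------------------------------------------------

def _pad_amounts(k: int, mode: str) -> tuple[int, int]:
    if mode == "valid":
        return 0, 0
    pl = (k - 1) // 2
    return pl, k - 1 - pl


def conv2d(x, w, b=None, pad: str = "same") -> Tensor:
    """2D cross-correlation, stride 1, NCHW.

    ``x``: (N, C, H, W); ``w``: (O, C, kh, kw); ``b``: (O,) or None;
    ``pad``: "same" (output spatial size preserved) or "valid".
    """
    x, w = as_tensor(x), as_tensor(w)
    if b is not None:
        b = as_tensor(b)
    kh, kw = w.shape[2], w.shape[3]
    pt, pb = _pad_amounts(kh, pad)
    pl, pr = _pad_amounts(kw, pad)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (N,C,Ho,Wo,kh,kw)
    out = np.tensordot(win, w.data, axes=([1, 4, 5], [1, 2, 3]))  # (N,Ho,Wo,O)
    out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
    if b is not None:
        out = out + b.data[None, :, None, None]

    def vjp(g):
        # g: (N,O,Ho,Wo)
        grad_w = np.tensordot(g, win, axes=([0, 2, 3], [0, 2, 3]))  # (O,C,kh,kw)
        wf = w.data[:, :, ::-1, ::-1]
        gp = np.pad(g, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
        gwin = sliding_window_view(gp, (kh, kw), axis=(2, 3))  # (N,O,Hp,Wp,kh,kw)
        gxp = np.tensordot(gwin, wf, axes=([1, 4, 5], [0, 2, 3]))  # (N,Hp,Wp,C)
        gxp = gxp.transpose(0, 3, 1, 2)
        H, W = x.shape[2], x.shape[3]
        gx = gxp[:, :, pt:pt + H, pl:pl + W]
        grads = [np.ascontiguousarray(gx), grad_w]
        if b is not None:
            grads.append(g.sum(axis=(0, 2, 3)))
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, _parents=parents, _vjp=vjp)


def depthwise_conv2d(x, w, b=None, pad: str = "same") -> Tensor:
    """Per-channel 2D cross-correlation (the depthwise half of a separable
    convolution).  ``x``: (N, C, H, W); ``w``: (C, kh, kw); ``b``: (C,)."""
    x, w = as_tensor(x), as_tensor(w)
    if b is not None:
        b = as_tensor(b)
    kh, kw = w.shape[1], w.shape[2]
    pt, pb = _pad_amounts(kh, pad)
    pl, pr = _pad_amounts(kw, pad)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (N,C,Ho,Wo,kh,kw)
    out = np.einsum("nchwij,cij->nchw", win, w.data, optimize=True)
    if b is not None:
        out = out + b.data[None, :, None, None]

    def vjp(g):
        grad_w = np.einsum("nchw,nchwij->cij", g, win, optimize=True)
        wf = w.data[:, ::-1, ::-1]
        gp = np.pad(g, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
        gwin = sliding_window_view(gp, (kh, kw), axis=(2, 3))
        gxp = np.einsum("nchwij,cij->nchw", gwin, wf, optimize=True)
        H, W = x.shape[2], x.shape[3]
        gx = gxp[:, :, pt:pt + H, pl:pl + W]
        grads = [np.ascontiguousarray(gx), grad_w]
        if b is not None:
            grads.append(g.sum(axis=(0, 2, 3)))
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, _parents=parents, _vjp=vjp)


def maxpool2d(x, pool: tuple[int, int] = (2, 2)) -> Tensor:
    """Non-overlapping max pooling by (h, w); spatial dims must divide."""
    x = as_tensor(x)
    h, w = pool
    N, C, H, W = x.shape
    if H % h or W % w:
        raise ValueError(f"spatial dims {(H, W)} not divisible by pool {(h, w)}")
    r = x.data.reshape(N, C, H // h, h, W // w, w).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(N, C, H // h, W // w, h * w)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def vjp(g):
        gr = np.zeros_like(r)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = gr.reshape(N, C, H // h, W // w, h, w).transpose(0, 1, 2, 4, 3, 5)
        return (gx.reshape(N, C, H, W),)

    return Tensor(out, _parents=(x,), _vjp=vjp)


def upsample_nearest(x, factor: tuple[int, int] = (2, 2)) -> Tensor:
    """Nearest-neighbour upsampling by integer factors."""
    x = as_tensor(x)
    h, w = factor
    out = x.data.repeat(h, axis=2).repeat(w, axis=3)
    N, C, H, W = x.shape

    def vjp(g):
        return (g.reshape(N, C, H, h, W, w).sum(axis=(3, 5)),)

    return Tensor(out, _parents=(x,), _vjp=vjp)


def concat(tensors: Sequence, axis: int = 1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out, _parents=tuple(ts), _vjp=vjp)


def global_avg_pool(x) -> Tensor:
    """(N, C, H, W) -> (N, C, 1, 1), mean over the spatial axes."""
    return tmean(x, axis=(2, 3), keepdims=True)
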