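"""Minimal reverse-mode automatic differentiation over numpy arrays.

The neural building blocks in this package (deformable convolution, SimAM,
BiC/SlimCSPSPPF fusion, the demo detector, the Wise-IoU training dynamics)
need gradients.  Rather than depending on a deep-learning framework, the
package carries this small tape-based autodiff: a :class:`Tensor` wraps an
``ndarray``, records the operations applied to it, and :meth:`Tensor.backward`
walks the tape in reverse topological order accumulating gradients.

Design notes
------------
* Broadcasting in binary operations is supported; gradients are summed back
  over broadcast axes (:func:`_unbroadcast`).
* ``conv2d`` (im2col) and ``grid_sample`` (bilinear, zero padding) are
  primitives with hand-written adjoints; everything else composes.
* ``detach`` cuts the tape — used to implement the starred (gradient-stopped)
  terms of the Wise-IoU loss.
* Float64 throughout: these blocks run at smoke-test scale where determinism
  and testability outrank speed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "conv2d", "grid_sample", "maximum", "minimum"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


class Tensor:
    """Array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")
    __array_priority__ = 100  # numpy defers binary ops to us

    def __init__(self, data, requires_grad: bool = False,
                 _prev: tuple = (), _backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._prev = _prev if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar Tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep graphs overflow recursion
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=float).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        grad = _unbroadcast(np.asarray(grad, dtype=float), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))
        out._backward = lambda g: (self._accum(g), other._accum(g))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))
        out._backward = lambda g: (self._accum(g * other.data),
                                   other._accum(g * self.data))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data / other.data, _prev=(self, other))
        out._backward = lambda g: (
            self._accum(g / other.data),
            other._accum(-g * self.data / other.data ** 2))
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    # -- elementwise functions -----------------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, _prev=(self,))
        out._backward = lambda g: self._accum(g * val)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, _prev=(self,))
        out._backward = lambda g: self._accum(g * 0.5 / np.maximum(val, 1e-12))
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(val, _prev=(self,))
        out._backward = lambda g: self._accum(g * val * (1 - val))
        return out

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(self.data * s, _prev=(self,))
        out._backward = lambda g: self._accum(g * (s + self.data * s * (1 - s)))
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, _prev=(self,))
        out._backward = lambda g: self._accum(g * (1 - val ** 2))
        return out

    def arctan(self):
        out = Tensor(np.arctan(self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g / (1 + self.data ** 2))
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g * np.sign(self.data))
        return out

    def clip(self, lo, hi):
        return minimum(maximum(self, lo), hi)

    # -- reductions / shaping ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _bw(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape))
        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def _bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        out._backward = _bw
        return out

    def pad2d(self, pad: int, value: float = 0.0):
        """Pad the last two axes by ``pad`` on each side with ``value``."""
        if pad == 0:
            return self
        width = [(0, 0)] * (self.data.ndim - 2) + [(pad, pad), (pad, pad)]
        out = Tensor(np.pad(self.data, width, constant_values=value), _prev=(self,))
        sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))
        out._backward = lambda g: self._accum(g[sl])
        return out

    def matmul(self, other):
        other = _as_tensor(other)
        out = Tensor(np.matmul(self.data, other.data), _prev=(self, other))

        def _bw(g):
            self._accum(np.matmul(g, np.swapaxes(other.data, -1, -2)))
            other._accum(np.matmul(np.swapaxes(self.data, -1, -2), g))
        out._backward = _bw
        return out

    __matmul__ = matmul


def maximum(a, b):
    """Elementwise maximum; subgradient routes to the winning argument."""
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(np.maximum(a.data, b.data), _prev=(a, b))
    mask = a.data >= b.data

    def _bw(g):
        a._accum(g * mask)
        b._accum(g * ~mask)
    out._backward = _bw
    return out


def minimum(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(np.minimum(a.data, b.data), _prev=(a, b))
    mask = a.data <= b.data

    def _bw(g):
        a._accum(g * mask)
        b._accum(g * ~mask)
    out._backward = _bw
    return out


def concat(tensors, axis: int = 0):
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])
    out._backward = _bw
    return out


def stack(tensors, axis: int = 0):
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))

    def _bw(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))
    out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# convolution primitive (im2col)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (x.shape[2] - k) // stride + 1
    wo = (x.shape[3] - k) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # n,c,ho,wo,k,k
    cols = windows.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int,
            ho: int, wo: int) -> np.ndarray:
    n, c, h, w = x_shape
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    cols = cols.reshape(n, c, k, k, ho, wo)
    for ki in range(k):
        for kj in range(k):
            xp[:, :, ki:ki + stride * ho:stride,
               kj:kj + stride * wo:stride] += cols[:, :, ki, kj]
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


def conv2d(x: "Tensor", w: "Tensor", b: "Tensor | None" = None,
           stride: int = 1, pad: int | None = None) -> "Tensor":
    """2-D convolution (cross-correlation), NCHW input, OIKK weights."""
    x, w = _as_tensor(x), _as_tensor(w)
    co, ci, k, k2 = w.data.shape
    assert k == k2, "square kernels only"
    if pad is None:
        pad = k // 2
    cols, ho, wo = _im2col(x.data, k, stride, pad)
    wmat = w.data.reshape(co, ci * k * k)
    y = np.matmul(wmat, cols).reshape(x.data.shape[0], co, ho, wo)
    prev = (x, w) if b is None else (x, w, b)
    if b is not None:
        y = y + b.data.reshape(1, co, 1, 1)
    out = Tensor(y, _prev=prev)

    def _bw(g):
        gmat = g.reshape(g.shape[0], co, ho * wo)
        w._accum(np.einsum("nop,ncp->oc", gmat, cols).reshape(w.data.shape))
        dcols = np.matmul(wmat.T, gmat)
        x._accum(_col2im(dcols, x.data.shape, k, stride, pad, ho, wo))
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))
    out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# bilinear grid sampling primitive (zero padding outside the map)
# ---------------------------------------------------------------------------

def grid_sample(x: "Tensor", coords: "Tensor") -> "Tensor":
    """Sample ``x`` (N,C,H,W) at fractional points ``coords`` (N,2,P) = (y,x).

    Bilinear interpolation of the four integer neighbors; samples whose
    support lies outside the map contribute zero (zero padding).  Returns a
    Tensor of shape (N,C,P), differentiable in both ``x`` and ``coords``.
    """
    x, coords = _as_tensor(x), _as_tensor(coords)
    n, c, h, w = x.data.shape
    py = coords.data[:, 0]  # (N,P)
    px = coords.data[:, 1]
    y0 = np.floor(py).astype(int)
    x0 = np.floor(px).astype(int)
    fy = py - y0
    fx = px - x0

    def gather(yi, xi):
        valid = (yi >= 0) & (yi < h) & (xi >= 0) & (xi < w)
        yc = np.clip(yi, 0, h - 1)
        xc = np.clip(xi, 0, w - 1)
        ni = np.arange(n)[:, None]
        vals = x.data[ni, :, yc, xi * 0 + xc]  # (N,P,C)
        return vals * valid[..., None], valid, yc, xc

    v00, m00, y00, x00 = gather(y0, x0)
    v01, m01, y01, x01 = gather(y0, x0 + 1)
    v10, m10, y10, x10 = gather(y0 + 1, x0)
    v11, m11, y11, x11 = gather(y0 + 1, x0 + 1)

    w00 = (1 - fy) * (1 - fx)
    w01 = (1 - fy) * fx
    w10 = fy * (1 - fx)
    w11 = fy * fx
    vals = (w00[..., None] * v00 + w01[..., None] * v01
            + w10[..., None] * v10 + w11[..., None] * v11)
    out = Tensor(vals.transpose(0, 2, 1), _prev=(x, coords))  # (N,C,P)

    def _bw(g):
        g = g.transpose(0, 2, 1)  # (N,P,C)
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            ni = np.arange(n)[:, None] * np.ones_like(y0)
            for wgt, msk, yc, xc in ((w00, m00, y00, x00), (w01, m01, y01, x01),
                                     (w10, m10, y10, x10), (w11, m11, y11, x11)):
                contrib = g * (wgt * msk)[..., None]  # (N,P,C)
                np.add.at(gx, (ni.ravel(),
                               slice(None),
                               yc.ravel(),
                               xc.ravel()),
                          contrib.reshape(-1, c))
            x._accum(gx)
        if coords.requires_grad:
            # d vals / d fy and d fx, then chain to coords
            dfy = ((-(1 - fx))[..., None] * v00 + (-fx)[..., None] * v01
                   + (1 - fx)[..., None] * v10 + fx[..., None] * v11)
            dfx = ((-(1 - fy))[..., None] * v00 + (1 - fy)[..., None] * v01
                   + (-fy)[..., None] * v10 + fy[..., None] * v11)
            gy = (g * dfy).sum(axis=-1)
            gxx = (g * dfx).sum(axis=-1)
            coords._accum(np.stack([gy, gxx], axis=1))
    out._backward = _bw
    return out
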