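"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the translation networks need: broadcasted
arithmetic, matrix multiplication, 2-D convolution (via im2col), pooling,
nearest-neighbour upsampling, pointwise nonlinearities and reductions.
Gradients are accumulated by a tape walk in reverse topological order.
All tensors are float32.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a gradient over axes that were broadcast in the forward op."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        a = np.asarray(data)
        # float32 by default; float64 is preserved (for high-precision
        # gradient verification), and promotes through ops as usual
        self.data = a if a.dtype == np.float64 else a.astype(np.float32, copy=False)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deeper than the recursion limit
            t, done = stack.pop()
            if done:
                topo.append(t)
                continue
            if id(t) in seen or not t.requires_grad:
                continue
            seen.add(id(t))
            stack.append((t, True))
            for p in t._parents:
                stack.append((p, False))
        self._accum(grad)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.float32(other))
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.float32(other))
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * np.float32(-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.float32(other))
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(np.float32(other)) + (-self)

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.float32(other))
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return Tensor(np.float32(other)) * self.pow(-1.0)

    def pow(self, p: float):
        out_data = self.data ** p

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        return Tensor._make(out_data, (self,), bw)

    def sqrt(self):
        return self.pow(0.5)

    # -- pointwise ------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(out_data, (self,), bw)

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        out_data = np.where(mask, self.data, slope * self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * np.where(mask, 1.0, slope).astype(self.data.dtype))

        return Tensor._make(out_data, (self,), bw)

    def sigmoid(self):
        x = self.data
        s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                     np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x)))).astype(x.dtype)

        def bw(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        return Tensor._make(s, (self,), bw)

    def tanh(self):
        t = np.tanh(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - t * t))

        return Tensor._make(t, (self,), bw)

    def softplus(self):
        out_data = np.logaddexp(0.0, self.data).astype(self.data.dtype)

        def bw(g):
            if self.requires_grad:
                self._accum(g / (1.0 + np.exp(-self.data)))

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        out_data = np.log(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(out_data, (self,), bw)

    def abs(self):
        sign = np.sign(self.data).astype(self.data.dtype)

        def bw(g):
            if self.requires_grad:
                self._accum(g * sign)

        return Tensor._make(np.abs(self.data), (self,), bw)

    def clip(self, lo: float, hi: float):
        mask = ((self.data > lo) & (self.data < hi)).astype(np.float32)
        out_data = np.clip(self.data, lo, hi)

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(out_data, (self,), bw)

    # -- reductions / shape ---------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if self.requires_grad:
                gg = np.asarray(g)
                if axis is not None and not keepdims:
                    ax = axis if isinstance(axis, tuple) else (axis,)
                    for a in sorted(a % self.data.ndim for a in ax):
                        gg = np.expand_dims(gg, a)
                self._accum(np.broadcast_to(gg, self.data.shape))

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * np.float32(1.0 / n)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        return Tensor._make(out_data, (self,), bw)

    def transpose(self, *axes):
        out_data = self.data.transpose(*axes)
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(*inv))

        return Tensor._make(out_data, (self,), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor._make(out_data, (self,), bw)

    # -- linear algebra --------------------------------------------------
    def matmul(self, other: "Tensor"):
        out_data = self.data @ other.data

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._make(out_data, (self, other), bw)

    __matmul__ = matmul

    # -- convolution and friends -----------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor" = None, stride: int = 1, pad: int = 0):
        """2-D convolution (cross-correlation), NCHW layout."""
        x, w = self.data, weight.data
        n, c, h, wd = x.shape
        co, ci, kh, kw = w.shape
        if ci != c:
            raise ValueError(f"channel mismatch: input {c}, weight expects {ci}")
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
        oh = (xp.shape[2] - kh) // stride + 1
        ow = (xp.shape[3] - kw) // stride + 1
        view = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
        cols = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * oh * ow, c * kh * kw
        )
        wmat = w.reshape(co, -1)
        out = cols @ wmat.T
        if bias is not None:
            out += bias.data
        out_data = out.reshape(n, oh, ow, co).transpose(0, 3, 1, 2)

        def bw(g):
            gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, co)
            if weight.requires_grad:
                weight._accum((gmat.T @ cols).reshape(w.shape))
            if bias is not None and bias.requires_grad:
                bias._accum(gmat.sum(axis=0))
            if self.requires_grad:
                gcols = (gmat @ wmat).reshape(n, oh, ow, c, kh, kw)
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += (
                            gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                        )
                self._accum(dxp[:, :, pad : pad + h, pad : pad + wd] if pad else dxp)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor._make(out_data, parents, bw)

    def avg_pool2d(self, k: int = 2):
        n, c, h, w = self.data.shape
        if h % k or w % k:
            raise ValueError(f"spatial dims {h}x{w} not divisible by pool size {k}")
        out_data = self.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

        def bw(g):
            if self.requires_grad:
                gg = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
                self._accum(gg)

        return Tensor._make(out_data, (self,), bw)

    def upsample_nearest(self, k: int = 2):
        out_data = np.repeat(np.repeat(self.data, k, axis=2), k, axis=3)

        def bw(g):
            if self.requires_grad:
                n, c, h, w = self.data.shape
                self._accum(g.reshape(n, c, h, k, w, k).sum(axis=(3, 5)))

        return Tensor._make(out_data, (self,), bw)


def concat(tensors, axis: int = 0) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, gg in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(gg)

    return Tensor._make(out_data, tuple(tensors), bw)
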