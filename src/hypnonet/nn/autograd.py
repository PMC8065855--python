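"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape-based engine: a :class:`Tensor` wraps an
``ndarray``, records the operations that produced it, and ``backward()``
walks the tape in reverse topological order accumulating gradients.  The
operation set is exactly what the sleep-staging network needs — elementwise
arithmetic, matmul, the transcendental functions behind Mish and softmax,
shape surgery (reshape / transpose / concatenate / pad / slice) and two
gather-style primitives used by strided and dilated convolution and by
max-pooling.

Everything runs in float64; the engine is single-threaded NumPy and is
sized for desk-scale experiments, not GPU workloads.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple = ()
        self.name = name

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        """Accumulate gradients of ``self`` w.r.t. every reachable leaf."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        self.grad = grad if self.grad is None else self.grad + grad

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return self._make(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            a._accum(-g)

        return self._make(-a.data, (a,), bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return self._make(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / b.data**2, b.data.shape))

        return self._make(a.data / b.data, (a, b), bwd)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        a = self

        def bwd(g):
            a._accum(g * p * a.data ** (p - 1))

        return self._make(a.data**p, (a,), bwd)

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))

        return self._make(a.data @ b.data, (a, b), bwd)

    # ---------------------------------------------------------- transcendental
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bwd(g):
            a._accum(g * out_data)

        return self._make(out_data, (a,), bwd)

    def log(self):
        a = self

        def bwd(g):
            a._accum(g / a.data)

        return self._make(np.log(a.data), (a,), bwd)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bwd(g):
            a._accum(g * (1.0 - out_data**2))

        return self._make(out_data, (a,), bwd)

    def softplus(self):
        """log(1 + e^x), computed without overflow for large |x|."""
        a = self
        out_data = np.logaddexp(0.0, a.data)

        def bwd(g):
            a._accum(g * _sigmoid(a.data))

        return self._make(out_data, (a,), bwd)

    def sigmoid(self):
        a = self
        out_data = _sigmoid(a.data)

        def bwd(g):
            a._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (a,), bwd)

    def clip_min(self, lo: float):
        """max(x, lo); gradient passes only where x > lo."""
        a = self
        mask = a.data > lo

        def bwd(g):
            a._accum(g * mask)

        return self._make(np.maximum(a.data, lo), (a,), bwd)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        a = self

        def bwd(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims=False):
        """Max along one axis; gradient flows to the (first) argmax."""
        a = self
        idx = np.argmax(a.data, axis=axis)
        out_data = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis)

        def bwd(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros_like(a.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), g, axis)
            a._accum(full)

        return self._make(out_data, (a,), bwd)

    # ------------------------------------------------------------ shape surgery
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bwd(g):
            a._accum(g.reshape(a.data.shape))

        return self._make(a.data.reshape(shape), (a,), bwd)

    def transpose(self, *axes):
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bwd(g):
            a._accum(g.transpose(inv))

        return self._make(a.data.transpose(axes), (a,), bwd)

    def __getitem__(self, key):
        a = self

        def bwd(g):
            full = np.zeros_like(a.data)
            np.add.at(full, key, g)
            a._accum(full)

        return self._make(a.data[key], (a,), bwd)

    def pad_axis(self, axis: int, before: int, after: int, value: float = 0.0):
        """Constant-pad one axis (used for 'same' convolution padding)."""
        a = self
        width = [(0, 0)] * a.data.ndim
        width[axis] = (before, after)
        sl = [slice(None)] * a.data.ndim
        sl[axis] = slice(before, before + a.data.shape[axis])
        sl = tuple(sl)

        def bwd(g):
            a._accum(g[sl])

        return self._make(
            np.pad(a.data, width, constant_values=value), (a,), bwd
        )

    def take_axis(self, indices: np.ndarray, axis: int):
        """Gather ``indices`` (any integer array) along ``axis``.

        The backward pass scatter-adds, so repeated indices — as produced
        by overlapping convolution windows — accumulate correctly.
        """
        a = self

        def bwd(g):
            full = np.zeros_like(a.data)
            sl = [slice(None)] * a.data.ndim
            sl[axis] = indices
            np.add.at(full, tuple(sl), g)
            a._accum(full)

        return self._make(np.take(a.data, indices, axis=axis), (a,), bwd)

    # ----------------------------------------------------------- compositions
    def softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def mish(self):
        """x * tanh(softplus(x)) — smooth non-monotonic activation."""
        return self * self.softplus().tanh()


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(out_data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._prev = tuple(tensors)
        out._backward = bwd
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]

    def bwd(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    out = Tensor(np.stack([t.data for t in tensors], axis=axis))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._prev = tuple(tensors)
        out._backward = bwd
    return out
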