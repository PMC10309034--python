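"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to it;
:meth:`Tensor.backward` walks the recorded graph in reverse topological order
and accumulates gradients into every tensor created with
``requires_grad=True``.  Only the primitives the network needs are provided;
convolutional operations live in :mod:`stnet.nn.functional`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "as_tensor", "cat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverses numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(
        i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1
    )
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_grad_owned")

    # make ndarray <op> Tensor defer to the Tensor reflected operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype.kind in "iub":
            arr = arr.astype(np.float64)
        self.data = arr
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._grad_owned = False
        self._backward = None
        self._parents = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        # first contribution is borrowed (no copy); later contributions force
        # ownership so a gradient array shared between nodes is never mutated
        if self.grad is None:
            self.grad = grad
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += grad
        else:
            self.grad = self.grad + grad
            self._grad_owned = True

    def zero_grad(self) -> None:
        self.grad = None
        self._grad_owned = False

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        if grad is None:
            grad = np.ones_like(self.data, dtype=np.float64)
        topo, seen, stack = [], set(), [(self, False)]
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out._parents:
            def bw(g, a=self, b=other):
                if a.requires_grad or a._parents:
                    a._accumulate(_unbroadcast(g, a.data.shape))
                if b.requires_grad or b._parents:
                    b._accumulate(_unbroadcast(g, b.data.shape))
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out._parents:
            out._backward = lambda g, a=self: a._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out._parents:
            def bw(g, a=self, b=other):
                if a.requires_grad or a._parents:
                    a._accumulate(_unbroadcast(g * b.data, a.data.shape))
                if b.requires_grad or b._parents:
                    b._accumulate(_unbroadcast(g * a.data, b.data.shape))
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = _make(self.data / other.data, (self, other))
        if out._parents:
            def bw(g, a=self, b=other):
                if a.requires_grad or a._parents:
                    a._accumulate(_unbroadcast(g / b.data, a.data.shape))
                if b.requires_grad or b._parents:
                    b._accumulate(
                        _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape)
                    )
            out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, n):
        if not np.isscalar(n):
            raise TypeError("only scalar exponents are supported")
        out = _make(np.power(self.data, n), (self,))
        if out._parents:
            def bw(g, a=self, n=n):
                if n == 0:
                    return
                a._accumulate(g * n * np.power(a.data, n - 1))
            out._backward = bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = _make(self.data @ other.data, (self, other))
        if out._parents:
            def bw(g, a=self, b=other):
                if a.requires_grad or a._parents:
                    ga = g @ np.swapaxes(b.data, -1, -2)
                    a._accumulate(_unbroadcast(ga, a.data.shape))
                if b.requires_grad or b._parents:
                    gb = np.swapaxes(a.data, -1, -2) @ g
                    b._accumulate(_unbroadcast(gb, b.data.shape))
            out._backward = bw
        return out

    # ---------------------------------------------------------- elementwise
    def exp(self):
        out = _make(np.exp(self.data), (self,))
        if out._parents:
            out._backward = lambda g, a=self, v=out.data: a._accumulate(g * v)
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out._parents:
            out._backward = lambda g, a=self: a._accumulate(g / a.data)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = _make(s, (self,))
        if out._parents:
            out._backward = lambda g, a=self, s=s: a._accumulate(g * s * (1 - s))
        return out

    def relu(self):
        mask = self.data > 0
        out = _make(np.where(mask, self.data, 0.0), (self,))
        if out._parents:
            out._backward = lambda g, a=self, m=mask: a._accumulate(g * m)
        return out

    def clamp(self, lo=None, hi=None):
        out_data = np.clip(self.data, lo, hi)
        out = _make(out_data, (self,))
        if out._parents:
            mask = np.ones_like(self.data, dtype=bool)
            if lo is not None:
                mask &= self.data > lo
            if hi is not None:
                mask &= self.data < hi
            # pass-through inside the interval, zero outside
            out._backward = lambda g, a=self, m=mask: a._accumulate(g * m)
        return out

    def maximum(self, other):
        other = as_tensor(other)
        out = _make(np.maximum(self.data, other.data), (self, other))
        if out._parents:
            mask = self.data >= other.data
            def bw(g, a=self, b=other, m=mask):
                if a.requires_grad or a._parents:
                    a._accumulate(_unbroadcast(g * m, a.data.shape))
                if b.requires_grad or b._parents:
                    b._accumulate(_unbroadcast(g * ~m, b.data.shape))
            out._backward = bw
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out._parents:
            def bw(g, a=self, axis=axis, keepdims=keepdims):
                if axis is not None and not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    g = np.expand_dims(g, axes)
                a._accumulate(np.broadcast_to(g, a.data.shape).copy())
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[i] for i in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis, keepdims=False):
        """Max over a single axis; gradient flows to the first argmax."""
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        out = _make(out_data, (self,))
        if out._parents:
            idx = np.expand_dims(self.data.argmax(axis=axis), axis)
            def bw(g, a=self, axis=axis, keepdims=keepdims, idx=idx):
                if not keepdims:
                    g = np.expand_dims(g, axis)
                grad = np.zeros_like(a.data, dtype=np.float64)
                np.put_along_axis(grad, idx, g, axis=axis)
                a._accumulate(grad)
            out._backward = bw
        return out

    # -------------------------------------------------------------- reshape
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out._parents:
            out._backward = lambda g, a=self: a._accumulate(
                g.reshape(a.data.shape)
            )
        return out

    def transpose(self, axes):
        out = _make(self.data.transpose(axes), (self,))
        if out._parents:
            inv = tuple(np.argsort(axes))
            out._backward = lambda g, a=self, inv=inv: a._accumulate(
                g.transpose(inv)
            )
        return out

    def __getitem__(self, key):
        out = _make(self.data[key], (self,))
        if out._parents:
            def bw(g, a=self, key=key):
                grad = np.zeros_like(a.data, dtype=np.float64)
                np.add.at(grad, key, g)
                a._accumulate(grad)
            out._backward = bw
        return out


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float64), requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: tuple) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = parents
    return out


def cat(tensors, axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis``."""
    tensors = [as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out._parents:
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)
        def bw(g, tensors=tensors, offsets=offsets, axis=axis):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad or t._parents:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accumulate(g[tuple(sl)])
        out._backward = bw
    return out
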