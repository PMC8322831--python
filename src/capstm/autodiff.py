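"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The matcher needs gradients through recurrent encoders, a soft-attention
block and an iterative routing procedure.  This module provides a small
tensor type that records the computation graph and back-propagates exact
gradients, plus an Adam optimizer.  Everything is float64: the test suite
checks layer outputs against scalar reference implementations at 1e-8 or
tighter, which single precision cannot honour.

Only the operations the model actually uses are implemented.  Gradients of
every primitive are exercised against central finite differences in the
test suite.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph recording (evaluation / prediction mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _sum_to(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to the shape of its source."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _result(data: np.ndarray, parents: tuple, backward) -> "Tensor":
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out.requires_grad = req
        out._parents = parents if req else ()
        out._backward = backward if req else None
        return out

    def _acc(self, g: np.ndarray) -> None:
        # grads are never mutated in place, so storing `g` directly is safe
        self.grad = g if self.grad is None else self.grad + g

    # -- basic info -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor({self.data!r}, requires_grad={self.requires_grad})"

    # -- autodiff driver ------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative topological sort: graphs from long recurrences are deep
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._acc(_sum_to(g, a.shape))
            if b.requires_grad:
                b._acc(_sum_to(g, b.shape))

        return Tensor._result(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            a._acc(-g)

        return Tensor._result(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._acc(_sum_to(g * b.data, a.shape))
            if b.requires_grad:
                b._acc(_sum_to(g * a.data, b.shape))

        return Tensor._result(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        a = self
        out_data = a.data ** exponent

        def bw(g):
            a._acc(g * exponent * a.data ** (exponent - 1))

        return Tensor._result(out_data, (a,), bw)

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self, other
        if a.data.ndim < 2 or b.data.ndim < 2:
            raise ValueError("matmul operands must be at least 2-D")

        def bw(g):
            if a.requires_grad:
                a._acc(_sum_to(g @ np.swapaxes(b.data, -1, -2), a.shape))
            if b.requires_grad:
                b._acc(_sum_to(np.swapaxes(a.data, -1, -2) @ g, b.shape))

        return Tensor._result(a.data @ b.data, (a, b), bw)

    # -- shaping --------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        src_shape = a.shape

        def bw(g):
            a._acc(g.reshape(src_shape))

        return Tensor._result(a.data.reshape(shape), (a,), bw)

    def transpose(self, axes):
        a = self
        inv = np.argsort(axes)

        def bw(g):
            a._acc(np.transpose(g, inv))

        return Tensor._result(np.transpose(a.data, axes), (a,), bw)

    def __getitem__(self, idx):
        a = self

        def bw(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._acc(full)

        return Tensor._result(a.data[idx], (a,), bw)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._acc(np.broadcast_to(g, a.shape).copy())

        return Tensor._result(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis: int, keepdims: bool = False):
        a = self
        out_data = a.data.max(axis=axis, keepdims=keepdims)

        def bw(g):
            expanded = out_data if keepdims else np.expand_dims(out_data, axis)
            hit = (a.data == expanded).astype(np.float64)
            hit /= hit.sum(axis=axis, keepdims=True)
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._acc(hit * g)

        return Tensor._result(out_data, (a,), bw)

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            a._acc(g * out_data)

        return Tensor._result(out_data, (a,), bw)

    def log(self):
        a = self

        def bw(g):
            a._acc(g / a.data)

        return Tensor._result(np.log(a.data), (a,), bw)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def bw(g):
            a._acc(g * 0.5 / out_data)

        return Tensor._result(out_data, (a,), bw)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bw(g):
            a._acc(g * (1.0 - out_data ** 2))

        return Tensor._result(out_data, (a,), bw)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60.0, 60.0)))

        def bw(g):
            a._acc(g * out_data * (1.0 - out_data))

        return Tensor._result(out_data, (a,), bw)

    def relu(self):
        a = self
        keep = (a.data > 0).astype(np.float64)

        def bw(g):
            a._acc(g * keep)

        return Tensor._result(a.data * keep, (a,), bw)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through unclipped entries."""
        a = self
        inside = ((a.data > lo) & (a.data < hi)).astype(np.float64)

        def bw(g):
            a._acc(g * inside)

        return Tensor._result(np.clip(a.data, lo, hi), (a,), bw)


# -- free functions -----------------------------------------------------------


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def zeros(shape, requires_grad: bool = False) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=requires_grad)


def concatenate(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(start, stop)
                t._acc(g[tuple(idx)])

    data = np.concatenate([t.data for t in tensors], axis=axis)
    return Tensor._result(data, tuple(tensors), bw)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def bw(g):
        for k, t in enumerate(tensors):
            if t.requires_grad:
                t._acc(np.take(g, k, axis=axis))

    data = np.stack([t.data for t in tensors], axis=axis)
    return Tensor._result(data, tuple(tensors), bw)


def softmax(x: Tensor, axis: int = -1, mask: np.ndarray | None = None) -> Tensor:
    """Numerically stable softmax; `mask` (0/1, broadcastable) zeroes entries.

    With a mask, rows that are entirely masked return all zeros instead of
    dividing by zero.
    """
    x = as_tensor(x)
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant: no grad needed
    e = (x - shift).exp()
    if mask is not None:
        e = e * Tensor(np.asarray(mask, dtype=np.float64))
        denom = e.sum(axis=axis, keepdims=True) + Tensor(1e-300)
    else:
        denom = e.sum(axis=axis, keepdims=True)
    return e / denom


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup `table[ids]` with scatter-add gradient into the table."""
    ids = np.asarray(ids)

    def bw(g):
        full = np.zeros_like(table.data)
        np.add.at(full, ids.reshape(-1), g.reshape(-1, table.data.shape[-1]))
        table._acc(full)

    return Tensor._result(table.data[ids], (table,), bw)


class Adam:
    """Adaptive-moment optimizer (the de-facto default for this model family)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
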