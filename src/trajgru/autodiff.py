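"""Minimal reverse-mode automatic differentiation over numpy arrays.

The forecasting network in this package is small (feature-level attention,
one modified GRU cell, two linear heads), so rather than depending on a deep
learning framework it is built on this self-contained tape-based engine.
Every operation needed by the model is implemented with a broadcast-aware
backward pass; gradients are accumulated into ``Tensor.grad`` by
:meth:`Tensor.backward` in reverse topological order.

The engine is validated by central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "sigmoid",
    "tanh",
    "relu",
    "exp",
    "softmax",
    "matmul",
]


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` (result of a broadcast op) back to ``shape``."""
    if grad.shape == shape:
        return grad
    # remove leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the tape bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- construction helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _sum_to_shape(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)

        def bwd(g):
            self._accumulate(g)
            other._accumulate(g)

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bwd(g):
            self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def bwd(g):
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)

        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)

        def bwd(g):
            self._accumulate(g / other.data)
            other._accumulate(-g * self.data / other.data**2)

        return Tensor(self.data / other.data, parents=(self, other), backward=bwd)

    def __matmul__(self, other) -> "Tensor":
        return matmul(self, other)

    def __getitem__(self, idx) -> "Tensor":
        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return Tensor(self.data[idx], parents=(self,), backward=bwd)

    # -- reductions / shaping -------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=bwd
        )

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bwd(g):
            self._accumulate(np.asarray(g).reshape(self.data.shape))

        return Tensor(self.data.reshape(shape), parents=(self,), backward=bwd)

    def square(self) -> "Tensor":
        return self * self

    # -- autodiff driver ------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))

        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product supporting batched (ndim >= 2) operands."""
    a, b = as_tensor(a), as_tensor(b)

    def bwd(g):
        a._accumulate(np.matmul(g, np.swapaxes(b.data, -1, -2)))
        b._accumulate(np.matmul(np.swapaxes(a.data, -1, -2), g))

    return Tensor(np.matmul(a.data, b.data), parents=(a, b), backward=bwd)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    parts = [as_tensor(t) for t in tensors]
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            p._accumulate(g[tuple(sl)])

    return Tensor(
        np.concatenate([p.data for p in parts], axis=axis),
        parents=tuple(parts),
        backward=bwd,
    )


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = 1.0 / (1.0 + np.exp(-x.data))

    def bwd(g):
        x._accumulate(g * out * (1.0 - out))

    return Tensor(out, parents=(x,), backward=bwd)


def tanh(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = np.tanh(x.data)

    def bwd(g):
        x._accumulate(g * (1.0 - out**2))

    return Tensor(out, parents=(x,), backward=bwd)


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)

    def bwd(g):
        x._accumulate(g * (x.data > 0))

    return Tensor(np.maximum(x.data, 0.0), parents=(x,), backward=bwd)


def absolute(x: Tensor) -> Tensor:
    x = as_tensor(x)

    def bwd(g):
        x._accumulate(g * np.sign(x.data))

    return Tensor(np.abs(x.data), parents=(x,), backward=bwd)


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = np.exp(x.data)

    def bwd(g):
        x._accumulate(g * out)

    return Tensor(out, parents=(x,), backward=bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis``."""
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        inner = (g * out).sum(axis=axis, keepdims=True)
        x._accumulate((g - inner) * out)

    return Tensor(out, parents=(x,), backward=bwd)
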