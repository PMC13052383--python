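"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the relevance model: broadcast-aware
arithmetic, matmul, concatenation, reductions, and the elementwise
nonlinearities the model uses.  Gradients are checked against central
finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "exp", "log", "sigmoid", "elu", "leaky_relu"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("value", "grad", "_parents", "_backward")
    __array_priority__ = 100  # keep numpy from hijacking the operators

    def __init__(
        self,
        value,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], tuple] | None = None,
    ):
        self.value = np.asarray(value, dtype=float)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.value.shape

    # -- graph traversal ---------------------------------------------------

    def backward(self) -> None:
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: Tensor) -> None:
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            order.append(node)

        visit(self)
        for node in order:
            node.grad = np.zeros_like(node.value)
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                parent.grad = parent.grad + g

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        return Tensor(
            self.value + other.value,
            (self, other),
            lambda g: (
                _unbroadcast(g, self.shape),
                _unbroadcast(g, other.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.value, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        return Tensor(
            self.value * other.value,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.value, self.shape),
                _unbroadcast(g * self.value, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return Tensor(
            self.value / other.value,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.value, self.shape),
                _unbroadcast(-g * self.value / other.value**2, other.shape),
            ),
        )

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        return Tensor(
            self.value**p,
            (self,),
            lambda g: (g * p * self.value ** (p - 1),),
        )

    def __matmul__(self, other):
        other = self._lift(other)
        return Tensor(
            self.value @ other.value,
            (self, other),
            lambda g: (g @ other.value.T, self.value.T @ g),
        )

    @property
    def T(self):
        return Tensor(self.value.T, (self,), lambda g: (g.T,))

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def back(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor(self.value.sum(axis=axis, keepdims=keepdims), (self,), back)

    def mean(self):
        return self.sum() * (1.0 / self.value.size)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.value.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(
        np.concatenate([t.value for t in tensors], axis=axis), tuple(tensors), back
    )


def exp(x: Tensor) -> Tensor:
    out_val = np.exp(x.value)
    return Tensor(out_val, (x,), lambda g: (g * out_val,))


def log(x: Tensor) -> Tensor:
    return Tensor(np.log(x.value), (x,), lambda g: (g / x.value,))


def sigmoid(x: Tensor) -> Tensor:
    out_val = 1.0 / (1.0 + np.exp(-x.value))
    return Tensor(out_val, (x,), lambda g: (g * out_val * (1.0 - out_val),))


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    out_val = np.where(x.value > 0, x.value, alpha * (np.exp(x.value) - 1.0))
    deriv = np.where(x.value > 0, 1.0, alpha * np.exp(x.value))
    return Tensor(out_val, (x,), lambda g: (g * deriv,))


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    out_val = np.where(x.value > 0, x.value, slope * x.value)
    deriv = np.where(x.value > 0, 1.0, slope)
    return Tensor(out_val, (x,), lambda g: (g * deriv,))
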