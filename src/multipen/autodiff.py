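"""Minimal reverse-mode automatic differentiation over numpy arrays.

The prognosis network is small (three squeeze-and-excitation gates plus a
bank of residual sub-models), so rather than depending on a full deep
learning framework this module provides exactly the differentiable
primitives that network needs: broadcasted arithmetic, batched matrix
products, ReLU / sigmoid / tanh, square root, reductions, reshape /
transpose and concatenation.  Layer normalisation and dropout are built
from these primitives where they are used.

Gradients follow the standard vector-Jacobian rules; broadcasting is
undone by summing over the broadcast axes.  All data is float64, which
makes eval-mode forward passes bitwise reproducible and keeps finite
difference checks tight.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "astensor", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast so it matches `shape`."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus an optional gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- bookkeeping ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _node(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def _accumulate(t: "Tensor", g: np.ndarray) -> None:
        if not t.requires_grad:
            return
        if t.grad is None:
            t.grad = np.zeros_like(t.data)
        t.grad += g

    def backward(self) -> None:
        """Backpropagate from a scalar output through the recorded graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = astensor(other)
        out_data = self.data + other.data

        def backward(g):
            Tensor._accumulate(self, _unbroadcast(g, self.data.shape))
            Tensor._accumulate(other, _unbroadcast(g, other.data.shape))

        return Tensor._node(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g):
            Tensor._accumulate(self, -g)

        return Tensor._node(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        other = astensor(other)
        out_data = self.data - other.data

        def backward(g):
            Tensor._accumulate(self, _unbroadcast(g, self.data.shape))
            Tensor._accumulate(other, _unbroadcast(-g, other.data.shape))

        return Tensor._node(out_data, (self, other), backward)

    def __rsub__(self, other) -> "Tensor":
        return astensor(other) - self

    def __mul__(self, other) -> "Tensor":
        other = astensor(other)
        out_data = self.data * other.data

        def backward(g):
            Tensor._accumulate(self, _unbroadcast(g * other.data, self.data.shape))
            Tensor._accumulate(other, _unbroadcast(g * self.data, other.data.shape))

        return Tensor._node(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = astensor(other)
        out_data = self.data / other.data

        def backward(g):
            Tensor._accumulate(self, _unbroadcast(g / other.data, self.data.shape))
            Tensor._accumulate(
                other,
                _unbroadcast(-g * self.data / (other.data * other.data), other.data.shape),
            )

        return Tensor._node(out_data, (self, other), backward)

    def __rtruediv__(self, other) -> "Tensor":
        return astensor(other) / self

    def __matmul__(self, other) -> "Tensor":
        other = astensor(other)
        if self.data.ndim < 2 or other.data.ndim < 2:
            raise ValueError("matmul operands must have at least 2 dimensions")
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            Tensor._accumulate(
                self,
                _unbroadcast(np.matmul(g, np.swapaxes(other.data, -1, -2)), self.data.shape),
            )
            Tensor._accumulate(
                other,
                _unbroadcast(np.matmul(np.swapaxes(self.data, -1, -2), g), other.data.shape),
            )

        return Tensor._node(out_data, (self, other), backward)

    # -- nonlinearities ------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0.0
        out_data = np.where(mask, self.data, 0.0)

        def backward(g):
            Tensor._accumulate(self, g * mask)

        return Tensor._node(out_data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        x = self.data
        # numerically stable logistic
        s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))), np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))

        def backward(g):
            Tensor._accumulate(self, g * s * (1.0 - s))

        return Tensor._node(s, (self,), backward)

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)

        def backward(g):
            Tensor._accumulate(self, g * (1.0 - t * t))

        return Tensor._node(t, (self,), backward)

    def sqrt(self) -> "Tensor":
        r = np.sqrt(self.data)

        def backward(g):
            Tensor._accumulate(self, g * 0.5 / r)

        return Tensor._node(r, (self,), backward)

    # -- reductions & reshaping ----------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            Tensor._accumulate(self, np.broadcast_to(gg, shape).copy())

        return Tensor._node(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.mean(axis=axis, keepdims=keepdims)
        shape = self.data.shape
        count = self.data.size / out_data.size

        def backward(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            Tensor._accumulate(self, np.broadcast_to(gg, shape) / count)

        return Tensor._node(out_data, (self,), backward)

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            Tensor._accumulate(self, g.reshape(orig))

        return Tensor._node(out_data, (self,), backward)

    def transpose(self, axes=None) -> "Tensor":
        if axes is None:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            Tensor._accumulate(self, g.transpose(inv))

        return Tensor._node(out_data, (self,), backward)

    def swap_last(self) -> "Tensor":
        """Transpose the last two axes (batched matrix transpose)."""
        axes = list(range(self.data.ndim))
        axes[-1], axes[-2] = axes[-2], axes[-1]
        return self.transpose(tuple(axes))


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            Tensor._accumulate(t, g[tuple(sl)])

    return Tensor._node(out_data, tuple(tensors), backward)


class Adam:
    """Adam optimizer over a list of parameter tensors (in-place updates)."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = [p for p in params if p.requires_grad]
        self.lr = float(lr)
        self.beta1 = float(beta1)
        self.beta2 = float(beta2)
        self.eps = float(eps)
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
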