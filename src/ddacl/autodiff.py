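"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the encoders, contrastive objective and
decoder need: broadcasting arithmetic, matmul, the usual point-wise
non-linearities, reductions, concatenation, row gather and segment sum.
Everything is float64. Gradients are accumulated by a topological sweep;
broadcasting is undone by summing gradients back to the operand shape.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "gather_rows", "segment_sum", "Adam", "xavier_uniform"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading dims numpy prepended
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over dims that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ utils
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # iterative topological order
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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

    # ------------------------------------------------------- binary operators
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _binary(self, other, fwd, bwd_self, bwd_other) -> "Tensor":
        other = Tensor._lift(other)
        out_data = fwd(self.data, other.data)
        req = self.requires_grad or other.requires_grad
        out = Tensor(out_data, requires_grad=req, _parents=(self, other))

        def _backward(g: np.ndarray) -> None:
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(bwd_self(g), self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(bwd_other(g), other.data.shape))

        out._backward = _backward
        return out

    def __add__(self, other):
        return self._binary(other, np.add, lambda g: g, lambda g: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, np.subtract, lambda g: g, lambda g: -g)

    def __rsub__(self, other):
        return Tensor._lift(other).__sub__(self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        return self._binary(other, np.multiply,
                            lambda g: g * other.data, lambda g: g * self.data)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        return self._binary(
            other, np.divide,
            lambda g: g / other.data,
            lambda g: -g * self.data / (other.data ** 2),
        )

    def __rtruediv__(self, other):
        return Tensor._lift(other).__truediv__(self)

    def __neg__(self):
        return self * (-1.0)

    def __matmul__(self, other):
        other = Tensor._lift(other)
        return self._binary(
            other, np.matmul,
            lambda g: g @ other.data.T,
            lambda g: self.data.T @ g,
        )

    def __pow__(self, p: float):
        assert np.isscalar(p)
        out = Tensor(self.data ** p, requires_grad=self.requires_grad, _parents=(self,))

        def _backward(g):
            self._accumulate(g * p * self.data ** (p - 1))

        out._backward = _backward
        return out

    # ---------------------------------------------------------------- unaries
    def _unary(self, out_data, grad_fn) -> "Tensor":
        out = Tensor(out_data, requires_grad=self.requires_grad, _parents=(self,))

        def _backward(g):
            self._accumulate(grad_fn(g))

        out._backward = _backward
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        return self._unary(e, lambda g: g * e)

    def log(self) -> "Tensor":
        return self._unary(np.log(self.data), lambda g: g / self.data)

    def sqrt(self) -> "Tensor":
        s = np.sqrt(self.data)
        return self._unary(s, lambda g: g * 0.5 / s)

    def relu(self) -> "Tensor":
        mask = self.data > 0
        return self._unary(self.data * mask, lambda g: g * mask)

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        scale = np.where(self.data > 0, 1.0, slope)
        return self._unary(self.data * scale, lambda g: g * scale)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        return self._unary(s, lambda g: g * s * (1.0 - s))

    def clip(self, lo: float, hi: float) -> "Tensor":
        # gradient passes only where the input is strictly inside the bounds
        mask = (self.data > lo) & (self.data < hi)
        return self._unary(np.clip(self.data, lo, hi), lambda g: g * mask)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def grad_fn(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, self.data.shape).copy()

        return self._unary(out_data, grad_fn)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    @property
    def T(self) -> "Tensor":
        return self._unary(self.data.T, lambda g: g.T)

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape
        return self._unary(self.data.reshape(*shape), lambda g: g.reshape(old))


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(out_data, requires_grad=req, _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(a, b)
            if t.requires_grad or t._parents:
                t._accumulate(g[tuple(idx)])

    out._backward = _backward
    return out


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows `idx` of `x`; backward scatter-adds into the source rows."""
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(x.data[idx], requires_grad=x.requires_grad, _parents=(x,))

    def _backward(g):
        acc = np.zeros_like(x.data)
        np.add.at(acc, idx, g)
        x._accumulate(acc)

    out._backward = _backward
    return out


def segment_sum(x: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of `x` into `num_segments` buckets given per-row segment ids."""
    segments = np.asarray(segments, dtype=np.intp)
    out_data = np.zeros((num_segments,) + x.data.shape[1:])
    np.add.at(out_data, segments, x.data)
    out = Tensor(out_data, requires_grad=x.requires_grad, _parents=(x,))

    def _backward(g):
        x._accumulate(g[segments])

    out._backward = _backward
    return out


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...] | None = None) -> np.ndarray:
    """Glorot/Xavier uniform initialization."""
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam optimizer over a list of Tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
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
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
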