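"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the fusion network needs: broadcast
arithmetic, (batched) matmul, relu/sigmoid/exp/log, masked softmax,
reductions, shape ops and dropout. Gradients are accumulated on a tape in
topological order. All data is float64; the networks here are small enough
that speed is not a concern and the extra precision keeps the oracle
comparisons tight.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "softmax"]


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reverse numpy broadcasting: reduce ``grad`` back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Run reverse accumulation from this (typically scalar) node."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be a few thousand nodes deep
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
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def back(g):
            if self.requires_grad:
                self._accumulate(_sum_to_shape(g, self.shape))
            if other.requires_grad:
                other._accumulate(_sum_to_shape(g, other.shape))

        return self._make(self.data + other.data, (self, other), back)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)

        def back(g):
            if self.requires_grad:
                self._accumulate(_sum_to_shape(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_sum_to_shape(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), back)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        return self * (other ** -1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * (self ** -1.0)

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def back(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return self._make(self.data ** exponent, (self,), back)

    def __matmul__(self, other):
        other = self._lift(other)

        def back(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_sum_to_shape(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_sum_to_shape(gb, other.shape))

        return self._make(self.data @ other.data, (self, other), back)

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def back(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return self._make(self.data * mask, (self,), back)

    def sigmoid(self):
        out_data = np.empty_like(self.data)
        pos = self.data >= 0
        out_data[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        ez = np.exp(self.data[~pos])
        out_data[~pos] = ez / (1.0 + ez)

        def back(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), back)

    def exp(self):
        out_data = np.exp(self.data)

        def back(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return self._make(out_data, (self,), back)

    def log(self):
        def back(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return self._make(np.log(self.data), (self,), back)

    def clip(self, lo: float, hi: float):
        """Clip values; gradient passes only through the interior."""
        inside = (self.data > lo) & (self.data < hi)

        def back(g):
            if self.requires_grad:
                self._accumulate(g * inside)

        return self._make(np.clip(self.data, lo, hi), (self,), back)

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def back(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), back)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        def back(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        return self._make(self.data.reshape(*shape), (self,), back)

    def swapaxes(self, a: int, b: int):
        def back(g):
            if self.requires_grad:
                self._accumulate(np.swapaxes(g, a, b))

        return self._make(np.swapaxes(self.data, a, b), (self,), back)

    def dropout(self, rate: float, rng: np.random.Generator):
        """Inverted dropout; identity when rate == 0."""
        if rate <= 0.0:
            return self
        keep = (rng.random(self.shape) >= rate) / (1.0 - rate)

        def back(g):
            if self.requires_grad:
                self._accumulate(g * keep)

        return self._make(self.data * keep, (self,), back)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)

        def back(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)

        out._backward = back
    return out


def softmax(x: Tensor, mask: np.ndarray | None = None, axis: int = -1) -> Tensor:
    """Numerically stable softmax over ``axis``.

    ``mask`` (same shape, 1 = valid) excludes positions from the
    distribution; rows with no valid position come out all-zero.
    """
    z = x.data
    if mask is not None:
        z = np.where(mask > 0, z, -np.inf)
    zmax = np.max(z, axis=axis, keepdims=True)
    zmax = np.where(np.isfinite(zmax), zmax, 0.0)
    ez = np.exp(z - zmax)
    denom = ez.sum(axis=axis, keepdims=True)
    out_data = np.divide(ez, denom, out=np.zeros_like(ez), where=denom > 0)

    out = Tensor(out_data)
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)

        def back(g):
            inner = (g * out_data).sum(axis=axis, keepdims=True)
            x._accumulate(out_data * (g - inner))

        out._backward = back
    return out
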