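"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for graph neural networks: broadcast arithmetic,
matmul, reductions, a couple of activations, row gather and segment-sum.
Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather_rows", "segment_sum"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- helpers ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def bwd(g, out):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), backward=lambda g, out: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def bwd(g, out):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def bwd(g, out):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor(self.data / other.data, parents=(self, other), backward=bwd)

    def __matmul__(self, other):
        other = self._wrap(other)

        def bwd(g, out):
            return (g @ other.data.T, self.data.T @ g)

        return Tensor(self.data @ other.data, parents=(self, other), backward=bwd)

    def square(self):
        return Tensor(
            self.data**2, parents=(self,), backward=lambda g, out: (2.0 * self.data * g,)
        )

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor(
            out_data, parents=(self,), backward=lambda g, out: (0.5 * g / np.maximum(out.data, 1e-12),)
        )

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bwd(g, out):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities --------------------------------------------------
    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        return Tensor(s, parents=(self,), backward=lambda g, out: (g * s * (1.0 - s),))

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        return Tensor(
            self.data * s,
            parents=(self,),
            backward=lambda g, out: (g * (s + self.data * s * (1.0 - s)),),
        )

    def tanh(self):
        th = np.tanh(self.data)
        return Tensor(th, parents=(self,), backward=lambda g, out: (g * (1.0 - th**2),))

    # -- autodiff --------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=float)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pg in zip(node._parents, node._backward(node.grad, node)):
                if not parent.requires_grad or pg is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad = parent.grad + pg


def concat(tensors, axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis``."""
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g, out):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors), backward=bwd
    )


def gather_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows ``t[idx]``; gradient scatters back with accumulation."""
    t = Tensor._wrap(t)
    idx = np.asarray(idx, dtype=int)

    def bwd(g, out):
        full = np.zeros_like(t.data)
        np.add.at(full, idx, g)
        return (full,)

    return Tensor(t.data[idx], parents=(t,), backward=bwd)


def segment_sum(t: Tensor, idx: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of ``t`` into ``n_segments`` buckets given per-row indices."""
    t = Tensor._wrap(t)
    idx = np.asarray(idx, dtype=int)
    out_data = np.zeros((n_segments,) + t.data.shape[1:])
    np.add.at(out_data, idx, t.data)

    def bwd(g, out):
        return (g[idx],)

    return Tensor(out_data, parents=(t,), backward=bwd)
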