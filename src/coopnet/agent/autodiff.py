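"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the graph network and the actor-critic loss
need: broadcasting add/mul, matmul (including batched), tanh, the
numerically stable log-sigmoid, sum/mean reductions, concatenation along
the last axis, reshape and broadcast. Gradients flow through a tape built
dynamically; ``backward()`` runs the tape in reverse topological order.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` to undo numpy broadcasting."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers -----------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req, parents=parents if req else (),
                      backward=backward if req else None)

    # -- ops -----------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def matmul(self, other):
        other = self._lift(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1:
                a2 = a[None, :]
                ga = np.matmul(g[..., None, :], np.swapaxes(b, -1, -2))[..., 0, :]
            else:
                ga = np.matmul(g, np.swapaxes(b, -1, -2))
            if b.ndim == 1:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g[..., None])[..., 0]
            else:
                a_t = np.swapaxes(a, -1, -2) if a.ndim >= 2 else a[:, None]
                gb = np.matmul(a_t, g)
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        return self._make(out_data, (self, other), backward)

    __matmul__ = matmul

    def tanh(self):
        out_data = np.tanh(self.data)
        return self._make(out_data, (self,), lambda g: (g * (1 - out_data**2),))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        return self._make(out_data, (self,), lambda g: (g * out_data * (1 - out_data),))

    def log_sigmoid(self):
        # log sigma(x) = -softplus(-x), stable for large |x|
        x = self.data
        out_data = -np.logaddexp(0.0, -x)
        sig_neg = 1.0 / (1.0 + np.exp(np.clip(x, -60, 60)))  # sigma(-x)
        return self._make(out_data, (self,), lambda g: (g * sig_neg,))

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            g2 = g
            if not keepdims:
                g2 = np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.data.shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        size = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / size)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        orig = self.data.shape
        return self._make(out_data, (self,), lambda g: (g.reshape(orig),))

    def broadcast_to(self, shape):
        out_data = np.broadcast_to(self.data, shape)
        orig = self.data.shape
        return self._make(out_data, (self,), lambda g: (_unbroadcast(g, orig),))

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- backward pass --------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for p, g in zip(node._parents, grads):
                if p.requires_grad:
                    if p.grad is None:
                        p.grad = np.zeros_like(p.data)
                    p.grad = p.grad + g


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    req = any(t.requires_grad for t in tensors)
    return Tensor(out_data, requires_grad=req,
                  parents=tuple(tensors) if req else (),
                  backward=backward if req else None)


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
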