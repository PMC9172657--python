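"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine: each :class:`Tensor` records the operation that
produced it and a closure that routes the upstream gradient to its inputs.
``Tensor.backward()`` topologically sorts the tape and accumulates gradients.
Everything is float32; shapes follow the NCHW convention for images.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- plumbing -----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def backward(self) -> None:
        """Backpropagate from this (scalar or any-shape) tensor, seed grad = 1."""
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._prev = (self, other)

            def _bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g, self.data.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g, other.data.shape))
            out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad)
        if out.requires_grad:
            out._prev = (self,)
            out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._prev = (self, other)

            def _bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g * other.data, self.data.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g * self.data, other.data.shape))
            out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad)
        if out.requires_grad:
            out._prev = (self,)
            out._backward = lambda g: self._accumulate(
                g * p * self.data ** (p - 1.0))
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._prev = (self, other)

            def _bw(g):
                if self.requires_grad:
                    self._accumulate(g @ other.data.swapaxes(-1, -2))
                if other.requires_grad:
                    other._accumulate(self.data.swapaxes(-1, -2) @ g)
            out._backward = _bw
        return out

    __matmul__ = matmul

    # -- shape ops ----------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = Tensor(self.data.reshape(shape), self.requires_grad)
        if out.requires_grad:
            out._prev = (self,)
            out._backward = lambda g: self._accumulate(g.reshape(orig))
        return out

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad)
        if out.requires_grad:
            out._prev = (self,)
            shape = self.data.shape

            def _bw(g):
                if axis is not None and not keepdims:
                    ax = axis if isinstance(axis, tuple) else (axis,)
                    g = np.expand_dims(g, ax)
                self._accumulate(np.broadcast_to(g, shape).astype(np.float32))
            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in
                     (axis if isinstance(axis, tuple) else (axis,))]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities -----------------------------------------------------

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad)
        if out.requires_grad:
            out._prev = (self,)
            mask = self.data > 0
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data),
                     self.requires_grad)
        if out.requires_grad:
            out._prev = (self,)
            factor = np.where(self.data > 0, 1.0, slope).astype(np.float32)
            out._backward = lambda g: self._accumulate(g * factor)
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, self.requires_grad)
        if out.requires_grad:
            out._prev = (self,)
            out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, self.requires_grad)
        if out.requires_grad:
            out._prev = (self,)
            out._backward = lambda g: self._accumulate(g * e)
        return out

    def log(self, eps: float = 0.0) -> "Tensor":
        x = self.data if eps == 0.0 else np.maximum(self.data, eps)
        out = Tensor(np.log(x), self.requires_grad)
        if out.requires_grad:
            out._prev = (self,)
            out._backward = lambda g: self._accumulate(g / np.maximum(x, 1e-30))
        return out

    def abs(self) -> "Tensor":
        out = Tensor(np.abs(self.data), self.requires_grad)
        if out.requires_grad:
            out._prev = (self,)
            sign = np.sign(self.data)
            out._backward = lambda g: self._accumulate(g * sign)
        return out

    def clamp(self, lo: float, hi: float) -> "Tensor":
        out = Tensor(np.clip(self.data, lo, hi), self.requires_grad)
        if out.requires_grad:
            out._prev = (self,)
            mask = ((self.data >= lo) & (self.data <= hi)).astype(np.float32)
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along ``axis`` with gradient routing back to each input."""
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis),
                 any(t.requires_grad for t in tensors))
    if out.requires_grad:
        out._prev = tuple(tensors)
        sizes = [d.shape[axis] for d in datas]
        splits = np.cumsum(sizes)[:-1]

        def _bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)
        out._backward = _bw
    return out
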