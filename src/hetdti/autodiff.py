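"""A minimal reverse-mode automatic differentiation engine on numpy arrays.

Supports exactly the operations the graph encoder needs: broadcasting
arithmetic, matrix products, ReLU/LeakyReLU/sigmoid nonlinearities, log and
sum reductions, a row-wise masked softmax (for attention over
neighborhoods) and row gathering (for pair lookup). Gradients are
accumulated by reverse topological sweep; everything is float64 and
single-threaded numpy, so runs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient down to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bwd)

    __matmul__ = matmul

    # -- nonlinearities ----------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), bwd)

    def leaky_relu(self, slope: float) -> "Tensor":
        pos = self.data > 0
        scale = np.where(pos, 1.0, slope)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * scale)

        return self._make(self.data * scale, (self,), bwd)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        return self._make(s, (self,), bwd)

    def log(self) -> "Tensor":
        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bwd)

    # -- reductions & indexing --------------------------------------------

    def sum(self) -> "Tensor":
        def bwd(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(self.data.sum(), (self,), bwd)

    def gather_rows(self, idx: np.ndarray) -> "Tensor":
        idx = np.asarray(idx, dtype=np.intp)

        def bwd(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, idx, g)
                self._accum(acc)

        return self._make(self.data[idx], (self,), bwd)

    def masked_softmax(self, mask: np.ndarray) -> "Tensor":
        """Row-wise softmax restricted to ``mask`` (True = participates).

        Masked-out entries are exactly zero in the output and receive no
        gradient. Every row must have at least one unmasked entry.
        """
        mask = np.asarray(mask, dtype=bool)
        z = np.where(mask, self.data, -np.inf)
        z = z - z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)

        def bwd(g):
            if self.requires_grad:
                dot = (g * p).sum(axis=-1, keepdims=True)
                self._accum(p * (g - dot))

        return self._make(p, (self,), bwd)
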