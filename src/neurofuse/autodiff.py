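"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the fusion and population-graph models
need: dense linear algebra, elementwise nonlinearities, row gathers and
segment sums for message passing on edge lists, and an Adam optimizer.
Gradients are accumulated by topological sort over the recorded tape.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import sparse

__all__ = ["Tensor", "Adam", "concat", "segment_sum", "gather_rows",
           "make_scatter"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus a gradient and a backward closure."""

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad", "name")

    def __init__(self, data, parents: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None,
                 requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.name = name

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def param(data, name: str = "") -> "Tensor":
        return Tensor(np.array(data, dtype=np.float64), requires_grad=True, name=name)

    @staticmethod
    def const(data) -> "Tensor":
        return Tensor(data)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph machinery ------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(g, self.data.shape))
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: training graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    def _binary(self, other, fwd, bwd_self, bwd_other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = fwd(self.data, other.data)
        out = Tensor(out_data, parents=(self, other))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(bwd_self(g), self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(bwd_other(g), other.data.shape))

        out._backward = backward
        return out

    def __add__(self, other):
        return self._binary(other, np.add, lambda g: g, lambda g: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, np.subtract, lambda g: g, lambda g: -g)

    def __rsub__(self, other):
        return Tensor(other).__sub__(self)

    def __mul__(self, other):
        other_t = other if isinstance(other, Tensor) else Tensor(other)
        return self._binary(other_t, np.multiply,
                            lambda g: g * other_t.data, lambda g: g * self.data)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other_t = other if isinstance(other, Tensor) else Tensor(other)
        return self._binary(
            other_t, np.divide,
            lambda g: g / other_t.data,
            lambda g: -g * self.data / (other_t.data ** 2))

    def __neg__(self):
        return self * (-1.0)

    def __matmul__(self, other):
        other_t = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data @ other_t.data, parents=(self, other_t))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g @ other_t.data.T)
            if other_t.requires_grad:
                other_t._accumulate(self.data.T @ g)

        out._backward = backward
        return out

    # -- elementwise ----------------------------------------------------------
    def _unary(self, fwd_data, local_grad) -> "Tensor":
        out = Tensor(fwd_data, parents=(self,))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * local_grad)

        out._backward = backward
        return out

    def relu(self) -> "Tensor":
        y = np.maximum(self.data, 0.0)
        return self._unary(y, (self.data > 0).astype(np.float64))

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        y = np.where(self.data > 0, self.data, slope * self.data)
        return self._unary(y, np.where(self.data > 0, 1.0, slope))

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))
        return self._unary(y, y * (1.0 - y))

    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        return self._unary(y, y)

    def log(self) -> "Tensor":
        return self._unary(np.log(self.data), 1.0 / self.data)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient passes through only inside the bounds."""
        y = np.clip(self.data, lo, hi)
        inside = ((self.data > lo) & (self.data < hi)).astype(np.float64)
        return self._unary(y, inside)

    # -- reductions / shape ---------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.full_like(self.data, float(g)))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = backward
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], parents=(self,))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward = backward
        return out


def make_scatter(ids: np.ndarray, n: int) -> sparse.csr_matrix:
    """(n x len(ids)) incidence matrix whose product scatter-adds rows."""
    ids = np.asarray(ids)
    e = len(ids)
    return sparse.csr_matrix((np.ones(e), (ids, np.arange(e))), shape=(n, e))


def _scatter_rows(scatter: sparse.csr_matrix, values: np.ndarray) -> np.ndarray:
    flat = scatter @ values.reshape(values.shape[0], -1)
    return np.asarray(flat).reshape((scatter.shape[0],) + values.shape[1:])


def gather_rows(t: Tensor, idx: np.ndarray,
                scatter: sparse.csr_matrix | None = None) -> Tensor:
    """Select rows `t[idx]`; the backward pass scatter-adds into the source.

    Pass the matching ``make_scatter(idx, n_rows)`` to reuse one sparse
    incidence matrix across the gathers and segment sums of a layer.
    """
    idx = np.asarray(idx)
    if scatter is None:
        return t[idx]
    out = Tensor(t.data[idx], parents=(t,))

    def backward(g: np.ndarray) -> None:
        if t.requires_grad:
            t._accumulate(_scatter_rows(scatter, g))

    out._backward = backward
    return out


def segment_sum(values: Tensor, segment_ids: np.ndarray, num_segments: int,
                scatter: sparse.csr_matrix | None = None) -> Tensor:
    """Sum rows of `values` into `num_segments` buckets given by `segment_ids`."""
    ids = np.asarray(segment_ids)
    if scatter is None:
        scatter = make_scatter(ids, num_segments)
    out = Tensor(_scatter_rows(scatter, values.data), parents=(values,))

    def backward(g: np.ndarray) -> None:
        if values.requires_grad:
            values._accumulate(g[ids])

    out._backward = backward
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: np.ndarray) -> None:
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(piece)

    out._backward = backward
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            m_hat = self._m[i] / (1 - self.b1 ** self.t)
            v_hat = self._v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
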