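"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The network architectures in this package need only a small closed set of
differentiable operations: dense and sparse matrix products, broadcasted
arithmetic, ReLU-family activations, exponentials, row gather/scatter and
segment reductions (the message-passing primitives of graph layers), and
concatenation.  This module provides exactly those on a ``Tensor`` wrapper
with a topologically-ordered backward pass, in float64 for reproducibility.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse


class Tensor:
    """A NumPy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        # First gradient is adopted without copying; a second contribution is
        # added out-of-place so aliased buffers (reshape views of a consumer's
        # gradient) are never mutated.
        if self.grad is None:
            self.grad = grad
        else:
            self.grad = self.grad + grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    def __radd__(self, other):
        return add(_wrap(other), self)

    def __sub__(self, other):
        return add(self, mul(_wrap(other), _wrap(-1.0)))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, _wrap(-1.0)))

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __rmul__(self, other):
        return mul(_wrap(other), self)

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __neg__(self):
        return mul(self, _wrap(-1.0))


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcasted gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, _parents=(a, b))

    def _backward():
        if a.requires_grad:
            a._accumulate(_unbroadcast(out.grad, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(out.grad, b.data.shape))

    out._backward = _backward
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, _parents=(a, b))

    def _backward():
        if a.requires_grad:
            a._accumulate(_unbroadcast(out.grad * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(out.grad * a.data, b.data.shape))

    out._backward = _backward
    return out


def div(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data / b.data, _parents=(a, b))

    def _backward():
        if a.requires_grad:
            a._accumulate(_unbroadcast(out.grad / b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-out.grad * a.data / b.data**2, b.data.shape))

    out._backward = _backward
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, _parents=(a, b))

    def _backward():
        if a.requires_grad:
            a._accumulate(out.grad @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ out.grad)

    out._backward = _backward
    return out


def spmm(matrix: sparse.spmatrix, x: Tensor) -> Tensor:
    """Product of a fixed (non-learned) sparse matrix with a tensor."""
    matrix = matrix.tocsr()
    out = Tensor(matrix @ x.data, _parents=(x,))

    def _backward():
        if x.requires_grad:
            x._accumulate(matrix.T @ out.grad)

    out._backward = _backward
    return out


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), _parents=(x,))

    def _backward():
        if x.requires_grad:
            x._accumulate(out.grad * (x.data > 0))

    out._backward = _backward
    return out


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    out = Tensor(np.where(x.data > 0, x.data, slope * x.data), _parents=(x,))

    def _backward():
        if x.requires_grad:
            x._accumulate(out.grad * np.where(x.data > 0, 1.0, slope))

    out._backward = _backward
    return out


def exp(x: Tensor) -> Tensor:
    out = Tensor(np.exp(x.data), _parents=(x,))

    def _backward():
        if x.requires_grad:
            x._accumulate(out.grad * out.data)

    out._backward = _backward
    return out


def reshape(x: Tensor, shape) -> Tensor:
    out = Tensor(x.data.reshape(shape), _parents=(x,))

    def _backward():
        if x.requires_grad:
            x._accumulate(out.grad.reshape(x.data.shape))

    out._backward = _backward
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(out.grad[tuple(sl)])

    out._backward = _backward
    return out


def gather_rows(x: Tensor, index: np.ndarray) -> Tensor:
    """Select rows ``x[index]``; backward scatter-adds into the source rows."""
    index = np.asarray(index, dtype=np.int64)
    out = Tensor(x.data[index], _parents=(x,))

    def _backward():
        if x.requires_grad:
            grad = np.zeros_like(x.data)
            np.add.at(grad, index, out.grad)
            x._accumulate(grad)

    out._backward = _backward
    return out


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``num_segments`` buckets given per-row ids."""
    segment_ids = np.asarray(segment_ids, dtype=np.int64)
    data = np.zeros((num_segments,) + x.data.shape[1:])
    np.add.at(data, segment_ids, x.data)
    out = Tensor(data, _parents=(x,))

    def _backward():
        if x.requires_grad:
            x._accumulate(out.grad[segment_ids])

    out._backward = _backward
    return out


def segment_max(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Columnwise maximum per segment; empty segments yield 0.

    The gradient flows to the first row attaining each maximum.
    """
    segment_ids = np.asarray(segment_ids, dtype=np.int64)
    data = np.full((num_segments,) + x.data.shape[1:], -np.inf)
    np.maximum.at(data, segment_ids, x.data)
    empty = ~np.isin(np.arange(num_segments), segment_ids)
    data[empty] = 0.0
    # first row index attaining the per-segment max, per column
    n_rows = x.data.shape[0]
    attains = x.data == data[segment_ids]
    candidates = np.where(attains, np.arange(n_rows)[:, None], n_rows)
    winner = np.full(data.shape, n_rows, dtype=np.int64)
    np.minimum.at(winner, segment_ids, candidates)
    out = Tensor(data, _parents=(x,))

    def _backward():
        if x.requires_grad:
            grad = np.zeros_like(x.data)
            valid = winner < n_rows
            seg_idx, col_idx = np.nonzero(valid)
            grad[winner[valid], col_idx] += out.grad[seg_idx, col_idx]
            x._accumulate(grad)

    out._backward = _backward
    return out


def segment_mean(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    segment_ids = np.asarray(segment_ids, dtype=np.int64)
    counts = np.bincount(segment_ids, minlength=num_segments).astype(np.float64)
    counts = np.maximum(counts, 1.0)[:, None]
    return mul(segment_sum(x, segment_ids, num_segments), Tensor(1.0 / counts))


def segment_softmax(scores: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of ``scores`` (shape (E, 1)) within each segment.

    The per-segment maximum is treated as a constant shift, the standard
    numerically stable formulation.
    """
    segment_ids = np.asarray(segment_ids, dtype=np.int64)
    shift = np.full(num_segments, -np.inf)
    np.maximum.at(shift, segment_ids, scores.data.ravel())
    shift[~np.isfinite(shift)] = 0.0
    z = exp(add(scores, Tensor(-shift[segment_ids][:, None])))
    denom = gather_rows(segment_sum(z, segment_ids, num_segments), segment_ids)
    return div(z, denom)


def mean(x: Tensor) -> Tensor:
    out = Tensor(np.array(x.data.mean()), _parents=(x,))

    def _backward():
        if x.requires_grad:
            x._accumulate(np.full_like(x.data, out.grad / x.data.size))

    out._backward = _backward
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return mul(x, Tensor(mask))
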