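"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical core beneath the point-cloud classifiers: a ``Tensor``
wrapping an ndarray, a closed set of differentiable operations (broadcasted
arithmetic, matmul, reductions, gather/scatter, segment max), and topological
back-propagation.  It is deliberately small - only what the two architectures
in this package need - and fully deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    # -- graph bookkeeping ------------------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        """Backpropagate from a scalar tensor."""
        assert self.data.size == 1, "backward() requires a scalar"
        topo, seen = [], set()

        def visit(t):
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

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._result(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        return self._result(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._result(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        return self._result(self.data / other.data, (self, other), bw)

    def __matmul__(self, other):
        other = self._lift(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._result(self.data @ other.data, (self, other), bw)

    def pow(self, p: float):
        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return self._result(self.data**p, (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * 0.5 / np.maximum(out_data, 1e-300))

        return self._result(out_data, (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._result(out_data, (self,), bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._result(np.log(self.data), (self,), bw)

    # -- nonlinearities ---------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._result(self.data * mask, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._result(out_data, (self,), bw)

    # -- reductions / shaping ---------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.full_like(self.data, 1.0) * g)
            else:
                g2 = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g2, self.data.shape).copy())

        return self._result(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        idx = np.argmax(self.data, axis=axis)
        out_data = np.max(self.data, axis=axis, keepdims=keepdims)

        def bw(g):
            if not self.requires_grad:
                return
            grad = np.zeros_like(self.data)
            g2 = g if not keepdims else np.squeeze(g, axis=axis)
            np.put_along_axis(
                grad, np.expand_dims(idx, axis), np.expand_dims(g2, axis), axis=axis
            )
            self._accum(grad)

        return self._result(out_data, (self,), bw)

    def reshape(self, *shape):
        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        return self._result(self.data.reshape(*shape), (self,), bw)

    @property
    def T(self):
        def bw(g):
            if self.requires_grad:
                self._accum(g.T)

        return self._result(self.data.T, (self,), bw)

    def take(self, indices):
        """Gather rows (axis 0)."""
        indices = np.asarray(indices)

        def bw(g):
            if self.requires_grad:
                grad = np.zeros_like(self.data)
                np.add.at(grad, indices, g)
                self._accum(grad)

        return self._result(self.data[indices], (self,), bw)

    def index_add(self, n_rows: int, indices):
        """Scatter-add rows of self into a (n_rows, ...) zero tensor."""
        indices = np.asarray(indices)
        out_data = np.zeros((n_rows,) + self.data.shape[1:], dtype=np.float64)
        np.add.at(out_data, indices, self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g[indices])

        return self._result(out_data, (self,), bw)

    def segment_max(self, segment_ids, n_segments: int):
        """Row-wise max over contiguous-labeled segments (axis 0).

        Rows of the output are the elementwise maxima of the input rows whose
        ``segment_ids`` match; empty segments yield 0.  Gradients flow to the
        (first) argmax row per segment and column.
        """
        segment_ids = np.asarray(segment_ids)
        n_cols = self.data.shape[1]
        out_data = np.full((n_segments, n_cols), -np.inf)
        np.maximum.at(out_data, segment_ids, self.data)
        empty = ~np.isfinite(out_data)
        out_data[empty] = 0.0
        # argmax per segment/column: first row achieving the max
        winner = np.zeros((n_segments, n_cols), dtype=np.int64)
        found = np.zeros((n_segments, n_cols), dtype=bool)
        order = np.argsort(segment_ids, kind="stable")
        for r in order:
            s = segment_ids[r]
            hit = (~found[s]) & (self.data[r] == out_data[s])
            winner[s][hit] = r
            found[s] |= hit

        def bw(g):
            if not self.requires_grad:
                return
            grad = np.zeros_like(self.data)
            gmask = g * found
            np.add.at(
                grad,
                (winner.ravel(), np.tile(np.arange(n_cols), n_segments)),
                gmask.ravel(),
            )
            self._accum(grad)

        return self._result(out_data, (self,), bw)

    @staticmethod
    def concat(tensors: list) -> "Tensor":
        """Concatenate 1-D tensors."""
        tensors = [Tensor._lift(t) for t in tensors]
        sizes = [t.data.size for t in tensors]
        bounds = np.cumsum([0] + sizes)

        def bw(g):
            for t, a, b in zip(tensors, bounds[:-1], bounds[1:]):
                if t.requires_grad:
                    t._accum(g[a:b].reshape(t.data.shape))

        return Tensor._result(
            np.concatenate([t.data.ravel() for t in tensors]), tuple(tensors), bw
        )

    # -- fused losses -----------------------------------------------------
    def log_softmax(self):
        """Row-wise log-softmax (2D input)."""
        shifted = self.data - self.data.max(axis=-1, keepdims=True)
        logsumexp = np.log(np.exp(shifted).sum(axis=-1, keepdims=True))
        out_data = shifted - logsumexp
        softmax = np.exp(out_data)

        def bw(g):
            if self.requires_grad:
                self._accum(g - softmax * g.sum(axis=-1, keepdims=True))

        return self._result(out_data, (self,), bw)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
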