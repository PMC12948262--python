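"""Compact reverse-mode automatic differentiation on NumPy arrays.

The graph-attention encoders and the fusion head in this package are small
enough that a dedicated tensor engine keeps the whole model stack dependency
free and single threaded (hence bitwise reproducible for a fixed seed).

Design notes
------------
* ``Tensor`` wraps a float64 ``ndarray``; every op records a closure that
  scatters the upstream gradient into its parents' ``grad`` buffers.
* Broadcasting is supported for elementwise ops; gradients are summed back
  down to the parent shape (``_unbroadcast``).
* Graph neural networks need three segment primitives: ``gather_rows``
  (edge-endpoint lookup), ``segment_sum`` (aggregation at a node) and
  ``segment_softmax`` (attention normalisation over each node's incoming
  edges). These are first-class ops with analytic backward passes.
* All parameters are float64. Model sizes here are tiny relative to the
  cost of Python dispatch, so there is no benefit to float32.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "parameter",
    "concat",
    "gather_rows",
    "segment_sum",
    "segment_mean",
    "segment_softmax",
    "SegmentContext",
    "segment_sum_ctx",
    "gather_rows_ctx",
    "segment_softmax_ctx",
    "Adam",
    "glorot",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(
        self,
        data,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = False,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in self._parents)
        self.grad: np.ndarray | None = None

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph traversal ------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient needs a scalar")
            grad = np.ones_like(self.data)
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        # out-of-place add: grad arrays may be shared between parents, so
        # never mutate an accumulated buffer in place
        self.grad = grad if self.grad is None else self.grad + grad

    # -- elementwise arithmetic ----------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return Tensor(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def bw(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor(self.data**exponent, (self,), bw)

    def __matmul__(self, other):
        other = as_tensor(other)
        if self.data.ndim != 2 or other.data.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor(self.data @ other.data, (self, other), bw)

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).astype(np.float64))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).astype(np.float64))

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- nonlinearities ---------------------------------------------------
    def exp(self):
        out = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * out)

        return Tensor(out, (self,), bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor(np.log(self.data), (self,), bw)

    def sqrt(self):
        out = np.sqrt(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out)

        return Tensor(out, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor(self.data * mask, (self,), bw)

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        factor = np.where(mask, 1.0, slope)

        def bw(g):
            if self.requires_grad:
                self._accum(g * factor)

        return Tensor(self.data * factor, (self,), bw)

    def elu(self, alpha: float = 1.0):
        neg = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out = np.where(self.data > 0, self.data, neg)

        def bw(g):
            if self.requires_grad:
                self._accum(g * np.where(self.data > 0, 1.0, neg + alpha))

        return Tensor(out, (self,), bw)

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out * (1.0 - out))

        return Tensor(out, (self,), bw)

    def __getitem__(self, key):
        def bw(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, key, g)
                self._accum(acc)

        return Tensor(self.data[key], (self,), bw)

    def reshape(self, *shape):
        orig = self.shape

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor(self.data.reshape(*shape), (self,), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> Tensor:
    """Glorot/Xavier-uniform initialised parameter."""
    fan_in, fan_out = (shape[0], shape[-1]) if len(shape) > 1 else (shape[0], shape[0])
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return parameter(rng.uniform(-limit, limit, size=shape))


# ---------------------------------------------------------------------------
# structural ops
# ---------------------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


def gather_rows(t: Tensor, index: np.ndarray) -> Tensor:
    """Row lookup ``t[index]`` with scatter-add backward."""
    index = np.asarray(index, dtype=np.intp)

    def bw(g):
        if t.requires_grad:
            acc = np.zeros_like(t.data)
            np.add.at(acc, index, g)
            t._accum(acc)

    return Tensor(t.data[index], (t,), bw)


def segment_sum(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``t`` into ``num_segments`` buckets given per-row ids."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out = np.zeros((num_segments,) + t.data.shape[1:], dtype=np.float64)
    np.add.at(out, segment_ids, t.data)

    def bw(g):
        if t.requires_grad:
            t._accum(g[segment_ids])

    return Tensor(out, (t,), bw)


def segment_mean(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    counts = np.bincount(segment_ids, minlength=num_segments).astype(np.float64)
    counts = np.maximum(counts, 1.0)
    s = segment_sum(t, segment_ids, num_segments)
    return s / Tensor(counts.reshape((-1,) + (1,) * (t.data.ndim - 1)))


def segment_softmax(scores: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of a 1-D score vector within each segment.

    Used for attention coefficients: ``segment_ids`` is the destination node
    of each edge, so each node's incoming-edge scores normalise to 1.
    """
    if scores.data.ndim != 1:
        raise ValueError("segment_softmax expects a 1-D score vector")
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    # numerically stable shift (constant w.r.t. gradient)
    seg_max = np.full(num_segments, -np.inf)
    np.maximum.at(seg_max, segment_ids, scores.data)
    shifted = scores.data - seg_max[segment_ids]
    e = np.exp(shifted)
    denom = np.zeros(num_segments)
    np.add.at(denom, segment_ids, e)
    alpha = e / denom[segment_ids]

    def bw(g):
        if scores.requires_grad:
            dot = np.zeros(num_segments)
            np.add.at(dot, segment_ids, alpha * g)
            scores._accum(alpha * (g - dot[segment_ids]))

    return Tensor(alpha, (scores,), bw)


# ---------------------------------------------------------------------------
# sorted-segment fast path
# ---------------------------------------------------------------------------

class SegmentContext:
    """Precomputed structure for segment ops over a fixed, sorted id vector.

    Requires ``ids`` sorted ascending with every segment in [0, n) present
    (graph encoders guarantee this by adding self-loops). ``reduceat`` then
    replaces scatter-adds in both directions.
    """

    def __init__(self, ids: np.ndarray, num_segments: int):
        ids = np.asarray(ids, dtype=np.intp)
        if np.any(np.diff(ids) < 0):
            raise ValueError("segment ids must be sorted ascending")
        uniq = np.unique(ids)
        if len(uniq) != num_segments or uniq[0] != 0 or uniq[-1] != num_segments - 1:
            raise ValueError("every segment in [0, n) must be present")
        self.ids = ids
        self.n = num_segments
        self.splits = np.searchsorted(ids, np.arange(num_segments))


def segment_sum_ctx(t: Tensor, ctx: SegmentContext) -> Tensor:
    out = np.add.reduceat(t.data, ctx.splits, axis=0)

    def bw(g):
        if t.requires_grad:
            t._accum(g[ctx.ids])

    return Tensor(out, (t,), bw)


def gather_rows_ctx(t: Tensor, ctx: SegmentContext) -> Tensor:
    """``t[ctx.ids]`` whose backward uses reduceat instead of scatter-add."""

    def bw(g):
        if t.requires_grad:
            acc = np.add.reduceat(g, ctx.splits, axis=0)
            if acc.shape[0] != t.data.shape[0]:
                # t has rows beyond the indexed segments; they get zero grad
                full = np.zeros_like(t.data)
                full[: acc.shape[0]] = acc
                acc = full
            t._accum(acc)

    return Tensor(t.data[ctx.ids], (t,), bw)


def segment_softmax_ctx(scores: Tensor, ctx: SegmentContext) -> Tensor:
    seg_max = np.maximum.reduceat(scores.data, ctx.splits)
    e = np.exp(scores.data - seg_max[ctx.ids])
    denom = np.add.reduceat(e, ctx.splits)
    alpha = e / denom[ctx.ids]

    def bw(g):
        if scores.requires_grad:
            dot = np.add.reduceat(alpha * g, ctx.splits)
            scores._accum(alpha * (g - dot[ctx.ids]))

    return Tensor(alpha, (scores,), bw)


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class Adam:
    """Adam with bias correction; operates in-place on Tensor parameters."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = [p for p in params if p.requires_grad]
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
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
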