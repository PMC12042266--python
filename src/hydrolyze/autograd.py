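"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Only the operations the reaction GNN needs are provided: dense algebra,
pointwise nonlinearities, row gather/scatter and segment reductions for
batched variable-size graphs. Gradients are checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
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

    # -- graph bookkeeping -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), back)

    __radd__ = __add__

    def __neg__(self):
        def back(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), back)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(
                    -g * self.data / other.data ** 2, other.data.shape))

        return Tensor._make(self.data / other.data, (self, other), back)

    def __pow__(self, p: float):
        def back(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(self.data ** p, (self,), back)

    def matmul(self, other: "Tensor") -> "Tensor":
        def back(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), back)

    __matmul__ = matmul

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def back(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.full_like(self.data, 1.0) * g)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims),
                            (self,), back)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- pointwise -----------------------------------------------------------
    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))

        def back(g):
            if self.requires_grad:
                self._accum(g * y * (1.0 - y))

        return Tensor._make(y, (self,), back)

    def tanh(self):
        y = np.tanh(self.data)

        def back(g):
            if self.requires_grad:
                self._accum(g * (1.0 - y * y))

        return Tensor._make(y, (self,), back)

    def relu(self):
        mask = self.data > 0

        def back(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), back)

    def abs(self):
        s = np.sign(self.data)

        def back(g):
            if self.requires_grad:
                self._accum(g * s)

        return Tensor._make(np.abs(self.data), (self,), back)

    def exp(self):
        y = np.exp(self.data)

        def back(g):
            if self.requires_grad:
                self._accum(g * y)

        return Tensor._make(y, (self,), back)


# -- structural ops ----------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), back)


def vstack(tensors: list[Tensor]) -> Tensor:
    return concat(tensors, axis=0)


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=np.int64)

    def back(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            np.add.at(gx, idx, g)
            x._accum(gx)

    return Tensor._make(x.data[idx], (x,), back)


def segment_sum(x: Tensor, seg: np.ndarray, n_segments: int) -> Tensor:
    seg = np.asarray(seg, dtype=np.int64)
    out = np.zeros((n_segments,) + x.data.shape[1:])
    np.add.at(out, seg, x.data)

    def back(g):
        if x.requires_grad:
            x._accum(g[seg])

    return Tensor._make(out, (x,), back)


def segment_mean(x: Tensor, seg: np.ndarray, n_segments: int) -> Tensor:
    counts = np.bincount(np.asarray(seg, dtype=np.int64),
                         minlength=n_segments).astype(np.float64)
    counts = np.maximum(counts, 1.0).reshape((-1,) + (1,) * (x.data.ndim - 1))
    return segment_sum(x, seg, n_segments) * Tensor(1.0 / counts)


def segment_softmax(scores: Tensor, seg: np.ndarray, n_segments: int) -> Tensor:
    """Softmax of a column vector within contiguous, sorted segments."""
    seg = np.asarray(seg, dtype=np.int64)
    s = scores.data.reshape(-1)
    # stable: subtract per-segment max
    seg_max = np.full(n_segments, -np.inf)
    np.maximum.at(seg_max, seg, s)
    e = np.exp(s - seg_max[seg])
    denom = np.zeros(n_segments)
    np.add.at(denom, seg, e)
    alpha = (e / denom[seg]).reshape(scores.data.shape)

    def back(g):
        if not scores.requires_grad:
            return
        gv = g.reshape(-1)
        av = alpha.reshape(-1)
        dot = np.zeros(n_segments)
        np.add.at(dot, seg, gv * av)
        scores._accum((av * (gv - dot[seg])).reshape(scores.data.shape))

    return Tensor._make(alpha, (scores,), back)


# -- parameters and optimizer -------------------------------------------------

def parameter(rng: np.random.Generator, shape: tuple, scale: str = "glorot") -> Tensor:
    if scale == "glorot":
        fan_in = shape[0] if len(shape) > 1 else shape[0]
        std = np.sqrt(2.0 / max(fan_in, 1))
        data = rng.normal(0.0, std, size=shape)
    elif scale == "zeros":
        data = np.zeros(shape)
    else:  # pragma: no cover
        raise ValueError(scale)
    return Tensor(data, requires_grad=True)


class Adam:
    """Standard Adam optimizer over a flat parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
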