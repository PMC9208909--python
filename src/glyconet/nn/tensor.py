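"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough surface for the models in this package: dense linear algebra,
pointwise nonlinearities, reductions, indexing/gather and segment
(scatter) operations for graph batching.  Gradients are accumulated in
float64 for numerical robustness; the graph is freed after ``backward``.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _is_advanced(idx) -> bool:
    if isinstance(idx, tuple):
        return any(_is_advanced(i) for i in idx)
    return isinstance(idx, (np.ndarray, list))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd --------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
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
            if node._backward is not None:
                node._backward(node.grad)
            # free graph references; keep leaf grads
            if node._parents:
                node._parents = ()
                node._backward = None
                node.grad = None

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data + other.data

        def bwd(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data * other.data

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        data = self.data ** p

        def bwd(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(data, (self,), bwd)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data @ other.data

        def bwd(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return Tensor._make(data, (self, other), bwd)

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(data, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int):
        idx = np.argmax(self.data, axis=axis)
        data = np.max(self.data, axis=axis)

        def bwd(g):
            full = np.zeros_like(self.data)
            grid = np.ogrid[tuple(slice(s) for s in data.shape)]
            sel = list(grid)
            sel.insert(axis, idx)
            full[tuple(sel)] = g
            self._accum(full)

        return Tensor._make(data, (self,), bwd)

    # -- pointwise -------------------------------------------------------
    def exp(self):
        data = np.exp(self.data)

        def bwd(g):
            self._accum(g * data)

        return Tensor._make(data, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bwd)

    def sqrt(self):
        data = np.sqrt(self.data)

        def bwd(g):
            self._accum(g * 0.5 / data)

        return Tensor._make(data, (self,), bwd)

    def tanh(self):
        data = np.tanh(self.data)

        def bwd(g):
            self._accum(g * (1.0 - data * data))

        return Tensor._make(data, (self,), bwd)

    def sigmoid(self):
        data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accum(g * data * (1.0 - data))

        return Tensor._make(data, (self,), bwd)

    def leaky_relu(self, slope: float = 0.01):
        mask = np.where(self.data > 0, 1.0, slope)

        def bwd(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bwd)

    # -- shape / indexing -----------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape

        def bwd(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), bwd)

    def __getitem__(self, idx):
        data = self.data[idx]
        advanced = _is_advanced(idx)

        def bwd(g):
            full = np.zeros_like(self.data)
            if advanced:
                np.add.at(full, idx, g)
            else:
                full[idx] += g
            self._accum(full)

        return Tensor._make(data, (self,), bwd)


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    return Tensor._make(data, tuple(tensors), bwd)


def scatter_sum(x: Tensor, index: np.ndarray, num: int) -> Tensor:
    """Sum rows of `x` into `num` buckets given per-row bucket ids."""
    out = np.zeros((num,) + x.data.shape[1:])
    np.add.at(out, index, x.data)

    def bwd(g):
        x._accum(g[index])

    return Tensor._make(out, (x,), bwd)


def scatter_mean(x: Tensor, index: np.ndarray, num: int) -> Tensor:
    counts = np.bincount(index, minlength=num).astype(np.float64)
    counts[counts == 0] = 1.0
    s = scatter_sum(x, index, num)
    return s * Tensor(1.0 / counts[:, None])


def scatter_max(x: Tensor, index: np.ndarray, num: int) -> Tensor:
    """Per-bucket feature-wise max; requires `index` sorted ascending."""
    n, d = x.data.shape
    boundaries = np.searchsorted(index, np.arange(num + 1))
    out = np.full((num, d), -np.inf)
    argrow = np.zeros((num, d), dtype=np.int64)
    for s in range(num):
        a, b = boundaries[s], boundaries[s + 1]
        if a == b:
            out[s] = 0.0
            continue
        block = x.data[a:b]
        loc = np.argmax(block, axis=0)
        out[s] = block[loc, np.arange(d)]
        argrow[s] = a + loc

    def bwd(g):
        full = np.zeros_like(x.data)
        nonempty = boundaries[:-1] < boundaries[1:]
        np.add.at(full, (argrow[nonempty].ravel(),
                         np.tile(np.arange(d), int(nonempty.sum()))),
                  g[nonempty].ravel())
        x._accum(full)

    return Tensor._make(out, (x,), bwd)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer `labels` under softmax(logits); fused for stability."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.data.shape[0]
    nll = -np.log(np.maximum(probs[np.arange(n), labels], 1e-300)).mean()

    def bwd(g):
        d = probs.copy()
        d[np.arange(n), labels] -= 1.0
        logits._accum(g * d / n)

    return Tensor._make(nll, (logits,), bwd)


def softmax(x: np.ndarray, axis: int = 1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=axis, keepdims=True)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw scores (log-sum-exp formulation)."""
    x = logits.data
    t = np.asarray(targets, dtype=np.float64)
    loss = (np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))).mean()
    n = x.size

    def bwd(g):
        p = 1.0 / (1.0 + np.exp(-x))
        logits._accum(g * (p - t) / n)

    return Tensor._make(loss, (logits,), bwd)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(target)
    return (diff * diff).mean()
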