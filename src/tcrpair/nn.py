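"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package's neural components (recurrent sequence acceptors, sequence
autoencoders, embedding tables, MLP heads) are small enough that a compact
tape-based engine is sufficient. Gradient correctness is checked against
central finite differences in the test suite.

All arrays are float64. Every op records its parents and a closure that
accumulates gradients into them; ``backward`` walks the tape in reverse
topological order.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as _sigmoid

__all__ = [
    "Tensor",
    "param",
    "constant",
    "matmul",
    "add",
    "mul",
    "concat",
    "hsplit",
    "sigmoid",
    "tanh",
    "leaky_relu",
    "embedding_lookup",
    "mean",
    "weighted_bce_logits",
    "softmax_xent_rows",
    "Adam",
]


class Tensor:
    """A node in the computation graph wrapping a numpy array."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)  # copy: g may be a view
        else:
            self.grad += g

    def backward(self):
        """Backpropagate from this (scalar) tensor through the tape."""
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
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def param(data) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return Tensor(out_data, (a, b), bwd)


def add(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise sum; ``b`` may broadcast as a bias row."""
    out_data = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, (a, b), bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, (a, b), bwd)


def _unbroadcast(g, shape):
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def concat(tensors, axis=1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor(out_data, tuple(tensors), bwd)


def hsplit(t: Tensor, n: int) -> list[Tensor]:
    """Split along axis 1 into ``n`` equal blocks (for gate unpacking)."""
    width = t.data.shape[1] // n
    outs = []
    for i in range(n):
        lo, hi = i * width, (i + 1) * width

        def bwd(g, lo=lo, hi=hi):
            if t.requires_grad:
                full = np.zeros_like(t.data)
                full[:, lo:hi] = g
                t._accumulate(full)

        outs.append(Tensor(t.data[:, lo:hi], (t,), bwd))
    return outs


def sigmoid(t: Tensor) -> Tensor:
    out_data = _sigmoid(t.data)

    def bwd(g):
        if t.requires_grad:
            t._accumulate(g * out_data * (1.0 - out_data))

    return Tensor(out_data, (t,), bwd)


def tanh(t: Tensor) -> Tensor:
    out_data = np.tanh(t.data)

    def bwd(g):
        if t.requires_grad:
            t._accumulate(g * (1.0 - out_data * out_data))

    return Tensor(out_data, (t,), bwd)


def leaky_relu(t: Tensor, negative_slope: float = 0.01) -> Tensor:
    out_data = np.where(t.data >= 0, t.data, negative_slope * t.data)

    def bwd(g):
        if t.requires_grad:
            t._accumulate(g * np.where(t.data >= 0, 1.0, negative_slope))

    return Tensor(out_data, (t,), bwd)


def embedding_lookup(table: Tensor, indices) -> Tensor:
    """Gather rows ``indices`` (1-D int array) from an embedding table."""
    idx = np.asarray(indices, dtype=np.intp)
    out_data = table.data[idx]

    def bwd(g):
        if table.requires_grad:
            full = np.zeros_like(table.data)
            np.add.at(full, idx, g)
            table._accumulate(full)

    return Tensor(out_data, (table,), bwd)


def mean(t: Tensor) -> Tensor:
    out_data = np.array(t.data.mean())
    n = t.data.size

    def bwd(g):
        if t.requires_grad:
            t._accumulate(np.full_like(t.data, float(g) / n))

    return Tensor(out_data, (t,), bwd)


def weighted_bce_logits(logits: Tensor, labels, weights) -> Tensor:
    """Per-sample weighted binary cross-entropy on raw logits.

    loss = mean_i w_i * (softplus(z_i) - y_i * z_i), the numerically stable
    form of w_i * BCE(sigmoid(z_i), y_i).
    """
    z = logits.data
    y = np.asarray(labels, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    softplus = np.logaddexp(0.0, z)
    out_data = np.array(np.mean(w * (softplus - y * z)))
    n = z.size

    def bwd(g):
        if logits.requires_grad:
            logits._accumulate(float(g) * w * (_sigmoid(z) - y) / n)

    return Tensor(out_data, (logits,), bwd)


def softmax_xent_rows(logits: Tensor, targets) -> Tensor:
    """Mean cross-entropy of row-wise softmax against integer targets.

    Used by the sequence autoencoder: each row is one sequence position over
    the symbol alphabet.
    """
    z = logits.data
    t = np.asarray(targets, dtype=np.intp)
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = z.shape[0]
    nll = -(z[np.arange(n), t] - zmax[:, 0] - np.log(ez.sum(axis=1)))
    out_data = np.array(nll.mean())

    def bwd(g):
        if logits.requires_grad:
            grad = p.copy()
            grad[np.arange(n), t] -= 1.0
            logits._accumulate(float(g) * grad / n)

    return Tensor(out_data, (logits,), bwd)


class Adam:
    """Adam with additive L2 regularization (classic, non-decoupled)."""

    def __init__(self, params: dict[str, Tensor], lr=1e-4, weight_decay=1e-5,
                 betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
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
            g = p.grad
            if g is None:
                continue
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
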