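"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine sized exactly for this package's transformer:
broadcast-aware elementwise arithmetic, batched matmul, reductions, softmax,
layer normalization, GELU, embedding lookup and the two classification
losses, all in float64.  Gradients are accumulated by topological backward
traversal from a scalar loss.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "tensor", "parameter"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


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

    # -- graph bookkeeping ---------------------------------------------------

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            # copy: the incoming buffer may be shared with another consumer
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad += grad

    def backward(self) -> None:
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
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------------

    def _binary(self, other, out_data, back):
        other = other if isinstance(other, Tensor) else Tensor(other)
        req = self.requires_grad or other.requires_grad
        return Tensor(out_data, req, (self, other), back(self, other)) if req else Tensor(out_data)

    def __add__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)

        def back(a, b):
            def fn(g):
                if a.requires_grad:
                    a._accumulate(_unbroadcast(g, a.data.shape))
                if b.requires_grad:
                    b._accumulate(_unbroadcast(g, b.data.shape))
            return fn

        return self._binary(o, self.data + o.data, back)

    __radd__ = __add__

    def __sub__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)

        def back(a, b):
            def fn(g):
                if a.requires_grad:
                    a._accumulate(_unbroadcast(g, a.data.shape))
                if b.requires_grad:
                    b._accumulate(_unbroadcast(-g, b.data.shape))
            return fn

        return self._binary(o, self.data - o.data, back)

    def __mul__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)

        def back(a, b):
            def fn(g):
                if a.requires_grad:
                    a._accumulate(_unbroadcast(g * b.data, a.data.shape))
                if b.requires_grad:
                    b._accumulate(_unbroadcast(g * a.data, b.data.shape))
            return fn

        return self._binary(o, self.data * o.data, back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)

        def back(a, b):
            def fn(g):
                if a.requires_grad:
                    a._accumulate(_unbroadcast(g / b.data, a.data.shape))
                if b.requires_grad:
                    b._accumulate(_unbroadcast(-g * a.data / b.data**2, b.data.shape))
            return fn

        return self._binary(o, self.data / o.data, back)

    def __neg__(self):
        return self * -1.0

    def __matmul__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)
        out = self.data @ o.data

        def fn(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(o.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if o.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                o._accumulate(_unbroadcast(gb, o.data.shape))

        req = self.requires_grad or o.requires_grad
        return Tensor(out, req, (self, o), fn) if req else Tensor(out)

    # -- shape ops -----------------------------------------------------------

    def reshape(self, *shape):
        src_shape = self.data.shape

        def fn(g):
            self._accumulate(g.reshape(src_shape))

        return Tensor(self.data.reshape(*shape), self.requires_grad, (self,),
                      fn if self.requires_grad else None)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def fn(g):
            self._accumulate(g.transpose(inv))

        return Tensor(self.data.transpose(axes), self.requires_grad, (self,),
                      fn if self.requires_grad else None)

    def __getitem__(self, idx):
        def fn(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return Tensor(self.data[idx], self.requires_grad, (self,),
                      fn if self.requires_grad else None)

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def fn(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad,
                      (self,), fn if self.requires_grad else None)

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- nonlinearities ------------------------------------------------------

    def gelu(self):
        x = self.data
        phi = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out = x * cdf

        def fn(g):
            self._accumulate(g * (cdf + x * phi))

        return Tensor(out, self.requires_grad, (self,), fn if self.requires_grad else None)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def fn(g):
            self._accumulate(g * s * (1.0 - s))

        return Tensor(s, self.requires_grad, (self,), fn if self.requires_grad else None)

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def fn(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accumulate(s * (g - dot))

        return Tensor(s, self.requires_grad, (self,), fn if self.requires_grad else None)

    def layer_norm(self, gain: "Tensor", bias: "Tensor", eps: float = 1e-5):
        """Normalize the last axis, then scale and shift."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv
        out = xhat * gain.data + bias.data

        def fn(g):
            if gain.requires_grad:
                gain._accumulate(_unbroadcast(g * xhat, gain.data.shape))
            if bias.requires_grad:
                bias._accumulate(_unbroadcast(g, bias.data.shape))
            if self.requires_grad:
                gx = g * gain.data
                n = x.shape[-1]
                dx = (gx - gx.mean(axis=-1, keepdims=True)
                      - xhat * (gx * xhat).mean(axis=-1, keepdims=True)) * inv
                self._accumulate(dx)

        req = self.requires_grad or gain.requires_grad or bias.requires_grad
        return Tensor(out, req, (self, gain, bias), fn if req else None)

    def dropout(self, p: float, rng: np.random.Generator):
        if p <= 0.0:
            return self
        keep = (rng.random(self.data.shape) >= p) / (1.0 - p)

        def fn(g):
            self._accumulate(g * keep)

        return Tensor(self.data * keep, self.requires_grad, (self,),
                      fn if self.requires_grad else None)


# ---------------------------------------------------------------------------
# free functions


def tensor(data) -> Tensor:
    return Tensor(data)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup with scatter-add gradient into the table."""
    ids = np.asarray(ids, dtype=np.int64)
    out = table.data[ids]

    def fn(g):
        full = np.zeros_like(table.data)
        np.add.at(full, ids, g)
        table._accumulate(full)

    return Tensor(out, table.requires_grad, (table,), fn if table.requires_grad else None)


def bce_with_logits(logits: Tensor, targets: np.ndarray, weights: np.ndarray | None = None) -> Tensor:
    """Mean binary cross-entropy on unnormalized logits; soft targets allowed."""
    z = logits.data
    y = np.asarray(targets, dtype=np.float64)
    # stable: max(z,0) - z*y + log(1 + exp(-|z|))
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    w = np.ones_like(loss) if weights is None else np.asarray(weights, dtype=np.float64)
    denom = max(w.sum(), 1.0)
    out = float((loss * w).sum() / denom)

    def fn(g):
        s = 1.0 / (1.0 + np.exp(-z))
        logits._accumulate(g * w * (s - y) / denom)

    return Tensor(out, logits.requires_grad, (logits,), fn if logits.requires_grad else None)


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy; `logits` is (n, K), `targets` int (n,)."""
    z = logits.data
    targets = np.asarray(targets, dtype=np.int64)
    n = z.shape[0]
    if n == 0:
        return Tensor(0.0)
    zmax = z.max(axis=-1, keepdims=True)
    lse = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=-1))
    picked = z[np.arange(n), targets]
    out = float(np.mean(lse - picked))

    def fn(g):
        p = np.exp(z - zmax)
        p /= p.sum(axis=-1, keepdims=True)
        p[np.arange(n), targets] -= 1.0
        logits._accumulate(g * p / n)

    return Tensor(out, logits.requires_grad, (logits,), fn if logits.requires_grad else None)


def xlogx_sum(p: Tensor) -> Tensor:
    """sum(p * log p) with the 0 log 0 = 0 convention."""
    data = p.data
    safe = np.where(data > 0, data, 1.0)
    out = float(np.sum(data * np.log(safe)))

    def fn(g):
        p._accumulate(g * (np.log(safe) + 1.0) * (data > 0))

    return Tensor(out, p.requires_grad, (p,), fn if p.requires_grad else None)
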