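"""Reverse-mode automatic differentiation on NumPy arrays.

A minimal tensor engine sufficient for transformer-style models: broadcastable
elementwise arithmetic, batched matmul, softmax/log-softmax, layer
normalization, GELU, embedding lookup, slicing, concatenation and reductions,
each with a hand-written backward rule.  Gradients are accumulated by a
topological sweep over the recorded computation graph.

Design notes
------------
* ``Tensor`` wraps a ``float64``/``float32`` ndarray; parameters are tensors
  with ``requires_grad=True``.
* Non-leaf gradients are discarded after ``backward`` unless the tensor was
  marked with :meth:`Tensor.retain_grad` (used by Grad-CAM to read gradients
  of attention probabilities).
* No in-place ops on tensors that participate in a graph.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np
from scipy.special import erf

ArrayLike = Union[np.ndarray, float, int]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_retain_grad", "name")

    def __init__(self, data: ArrayLike, requires_grad: bool = False,
                 name: str = ""):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: tuple = ()
        self._retain_grad = False
        self.name = name

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def retain_grad(self) -> "Tensor":
        self._retain_grad = True
        return self

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this tensor (scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() on non-scalar needs an explicit grad")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor"):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    if id(p) not in seen:
                        stack.append((p, False))

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and (node._backward is None or node._retain_grad):
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if not parent.requires_grad:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg

    # ------------------------------------------------------------- operations
    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], list]) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = _GRAD_ENABLED and any(p.requires_grad
                                                  for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def __add__(self, other):
        other = as_tensor(other)
        def bw(g):
            return [(self, _unbroadcast(g, self.data.shape)),
                    (other, _unbroadcast(g, other.data.shape))]
        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        def bw(g):
            return [(self, _unbroadcast(g * other.data, self.data.shape)),
                    (other, _unbroadcast(g * self.data, other.data.shape))]
        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        def bw(g):
            return [(self, _unbroadcast(g / other.data, self.data.shape)),
                    (other, _unbroadcast(-g * self.data / other.data ** 2,
                                         other.data.shape))]
        return self._make(self.data / other.data, (self, other), bw)

    def __pow__(self, p: float):
        def bw(g):
            return [(self, g * p * self.data ** (p - 1))]
        return self._make(self.data ** p, (self,), bw)

    def __matmul__(self, other):
        other = as_tensor(other)
        def bw(g):
            a, b = self.data, other.data
            a2 = a.reshape(1, -1) if a.ndim == 1 else a
            b2 = b.reshape(-1, 1) if b.ndim == 1 else b
            g2 = g
            if a.ndim == 1:
                g2 = np.expand_dims(g2, -2)
            if b.ndim == 1:
                g2 = np.expand_dims(g2, -1)
            ga = g2 @ np.swapaxes(b2, -1, -2)
            gb = np.swapaxes(a2, -1, -2) @ g2
            if a.ndim == 1:
                ga = np.squeeze(ga, -2)
            if b.ndim == 1:
                gb = np.squeeze(gb, -1)
            return [(self, _unbroadcast(ga, a.shape)),
                    (other, _unbroadcast(gb, b.shape))]
        return self._make(self.data @ other.data, (self, other), bw)

    def __getitem__(self, idx):
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return [(self, full)]
        return self._make(self.data[idx], (self,), bw)

    def reshape(self, *shape):
        orig = self.data.shape
        def bw(g):
            return [(self, g.reshape(orig))]
        return self._make(self.data.reshape(*shape), (self,), bw)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        def bw(g):
            return [(self, g.transpose(inv))]
        return self._make(self.data.transpose(axes), (self,), bw)

    def swapaxes(self, a: int, b: int):
        def bw(g):
            return [(self, np.swapaxes(g, a, b))]
        return self._make(np.swapaxes(self.data, a, b), (self,), bw)

    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if axis is None:
                return [(self, np.broadcast_to(g, self.data.shape).copy())]
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            return [(self, np.broadcast_to(gg, self.data.shape).copy())]
        return self._make(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def exp(self):
        out_data = np.exp(self.data)
        def bw(g):
            return [(self, g * out_data)]
        return self._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            return [(self, g / self.data)]
        return self._make(np.log(self.data), (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)
        def bw(g):
            return [(self, g * (1.0 - out_data ** 2))]
        return self._make(out_data, (self,), bw)

    def relu(self):
        def bw(g):
            return [(self, g * (self.data > 0))]
        return self._make(np.maximum(self.data, 0.0), (self,), bw)

    def gelu(self):
        """Exact (erf-based) Gaussian error linear unit."""
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        def bw(g):
            return [(self, g * (cdf + x * pdf))]
        return self._make(x * cdf, (self,), bw)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)
        def bw(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            return [(self, out_data * (g - dot))]
        return self._make(out_data, (self,), bw)

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out_data = z - lse
        sm = np.exp(out_data)
        def bw(g):
            return [(self, g - sm * g.sum(axis=axis, keepdims=True))]
        return self._make(out_data, (self,), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    out.requires_grad = _GRAD_ENABLED and any(t.requires_grad for t in tensors)
    if out.requires_grad:
        splits = np.cumsum(sizes)[:-1]
        def bw(g):
            parts = np.split(g, splits, axis=axis)
            return list(zip(tensors, parts))
        out._parents = tuple(tensors)
        out._backward = bw
    return out


def embedding_lookup(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row gather ``weight[ids]`` with scatter-add backward."""
    ids = np.asarray(ids, dtype=np.int64)
    def bw(g):
        full = np.zeros_like(weight.data)
        np.add.at(full, ids, g)
        return [(weight, full)]
    out = Tensor(weight.data[ids])
    out.requires_grad = _GRAD_ENABLED and weight.requires_grad
    if out.requires_grad:
        out._parents = (weight,)
        out._backward = bw
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc ** 2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(xhat * gamma.data + beta.data)
    out.requires_grad = _GRAD_ENABLED and (
        x.requires_grad or gamma.requires_grad or beta.requires_grad)
    if out.requires_grad:
        D = x.data.shape[-1]
        def bw(g):
            dgamma = _unbroadcast(g * xhat, gamma.data.shape)
            dbeta = _unbroadcast(g, beta.data.shape)
            gx = g * gamma.data
            dx = inv * (gx - gx.mean(axis=-1, keepdims=True)
                        - xhat * (gx * xhat).mean(axis=-1, keepdims=True))
            return [(x, dx), (gamma, dgamma), (beta, dbeta)]
        out._parents = (x, gamma, beta)
        out._backward = bw
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when ``training`` is False or p == 0."""
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


def cross_entropy_logits(logits: Tensor, targets: np.ndarray,
                         mask: Optional[np.ndarray] = None) -> Tensor:
    """Mean cross-entropy of integer ``targets`` under ``logits`` rows.

    ``logits``: (..., V); ``targets``: integer array matching the leading
    shape; ``mask``: optional 0/1 weights — masked-out positions contribute
    nothing and do not enter the mean.
    """
    targets = np.asarray(targets, dtype=np.int64)
    logp = logits.log_softmax(axis=-1)
    flat = logp.reshape(-1, logits.shape[-1])
    idx = (np.arange(flat.shape[0]), targets.reshape(-1))
    picked = flat[idx]
    if mask is None:
        return -picked.mean()
    w = np.asarray(mask, dtype=np.float64).reshape(-1)
    denom = max(w.sum(), 1.0)
    return -(picked * Tensor(w)).sum() * (1.0 / denom)
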