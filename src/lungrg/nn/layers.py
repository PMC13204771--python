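"""Neural-network building blocks on top of the autodiff engine.

Initialization conventions: linear layers use truncated-normal weights
(sigma 0.02) with zero bias, matching common transformer practice; learnable
query banks use Xavier-uniform (see the pooling module).
"""

from __future__ import annotations

from typing import Dict, Iterator, Optional, Tuple

import numpy as np

from .tensor import Tensor, concat, dropout, embedding_lookup, layer_norm


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02,
                 bound: float = 2.0) -> np.ndarray:
    """Truncated normal init: resample draws beyond ``bound`` sigmas."""
    x = rng.normal(0.0, std, size=shape)
    bad = np.abs(x) > bound * std
    while bad.any():
        x[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(x) > bound * std
    return x


def xavier_uniform(rng: np.random.Generator, shape) -> np.ndarray:
    fan_in, fan_out = shape[-2] if len(shape) > 1 else shape[-1], shape[-1]
    a = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-a, a, size=shape)


class Module:
    """Base class with parameter registry, train/eval mode and a dropout RNG."""

    def __init__(self):
        self._params: Dict[str, Tensor] = {}
        self._modules: Dict[str, "Module"] = {}
        self.training = True
        self._rng = np.random.default_rng(0)

    def __setattr__(self, key, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[key] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[key] = value
        object.__setattr__(self, key, value)

    def register(self, key: str, module: "Module") -> "Module":
        self._modules[key] = module
        object.__setattr__(self, key.replace(".", "_"), module)
        return module

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Tensor]]:
        for k, p in self._params.items():
            yield (f"{prefix}{k}", p)
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{k}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def set_rng(self, rng: np.random.Generator):
        self._rng = rng
        for m in self._modules.values():
            m.set_rng(rng)
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)[:5]}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data[...] = arr


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Tensor(trunc_normal(rng, (in_dim, out_dim)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, self.eps)


class Embedding(Module):
    def __init__(self, num: int, dim: int, rng: np.random.Generator,
                 std: float = 0.02):
        super().__init__()
        self.weight = Tensor(trunc_normal(rng, (num, dim), std=std),
                             requires_grad=True)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return embedding_lookup(self.weight, ids)


class MultiHeadAttention(Module):
    """Multi-head attention with separate biased Q/K/V/O projections.

    ``forward`` accepts pre-normalized (or raw) query/key/value inputs of
    shape (Tq, D) / (Tk, D) and returns the attended output together with the
    post-softmax attention probabilities (heads, Tq, Tk), which callers may
    ``retain_grad`` for gradient-based attribution.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 attn_dropout: float = 0.0):
        super().__init__()
        if dim % heads:
            raise ValueError("embed dim must be divisible by head count")
        self.dim, self.heads, self.head_dim = dim, heads, dim // heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)
        self.attn_dropout = attn_dropout

    def __call__(self, q_in: Tensor, k_in: Tensor, v_in: Tensor,
                 mask: Optional[np.ndarray] = None) -> Tuple[Tensor, Tensor]:
        tq, tk = q_in.shape[-2], k_in.shape[-2]
        h, hd = self.heads, self.head_dim
        # (T, D) -> (h, T, hd)
        q = self.wq(q_in).reshape(tq, h, hd).swapaxes(0, 1)
        k = self.wk(k_in).reshape(tk, h, hd).swapaxes(0, 1)
        v = self.wv(v_in).reshape(tk, h, hd).swapaxes(0, 1)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(hd))
        if mask is not None:
            scores = scores + Tensor(mask)
        probs = scores.softmax(axis=-1)
        attn = dropout(probs, self.attn_dropout, self._rng, self.training)
        out = (attn @ v).swapaxes(0, 1).reshape(tq, self.dim)
        return self.wo(out), probs


class MLP(Module):
    """Position-wise feed-forward block: Linear -> GELU -> Linear."""

    def __init__(self, dim: int, ratio: int, rng: np.random.Generator,
                 p_dropout: float = 0.0):
        super().__init__()
        self.fc1 = Linear(dim, dim * ratio, rng)
        self.fc2 = Linear(dim * ratio, dim, rng)
        self.p_dropout = p_dropout

    def __call__(self, x: Tensor) -> Tensor:
        h = self.fc1(x).gelu()
        h = dropout(h, self.p_dropout, self._rng, self.training)
        return self.fc2(h)
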