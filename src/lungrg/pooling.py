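"""Cross-slice aggregation with learnable query attention pooling (LQAP).

The five per-slice token sequences (197 x 768 each) are concatenated into a
985-token bank.  A bank of trainable latent queries (197 for the latent
stage, a single class query for the patient stage) attends over it:

    Z' = MHA(LN(Q), LN(X), LN(X)) + Q
    Z  = MLP(LN(Z')) + Z'

Query, key and value inputs pass through *independent* LayerNorms; the
residual adds the raw (pre-norm) queries.  Attention over the key set makes
the pooled output invariant to the ordering of slice blocks.  Simple mean /
max / single-head attention pools are provided as ablation baselines; they
produce a single vector and cannot feed a cross-attention decoder.

Parameter totals at the default width: latent pool 7,242,240 (7.24 M),
patient pool 7,091,712 (7.09 M), 14,333,952 combined (14.33 M).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .nn import (MLP, LayerNorm, Linear, Module, MultiHeadAttention, Tensor,
                 concat, dropout, xavier_uniform)

CLASS_NAMES = ("Normal", "SCLC", "NSCLC")


@dataclass(frozen=True)
class LatentPoolConfig:
    n_latent: int = 197
    embed_dim: int = 768
    heads: int = 12
    mlp_ratio: int = 4
    dropout: float = 0.1

    def __post_init__(self):
        if self.n_latent < 1:
            raise ValueError("n_latent must be >= 1")


def concat_slices(per_slice: Sequence[Tensor], n_slices: int = 5) -> Tensor:
    """Concatenate per-slice token sequences along the token dimension."""
    if len(per_slice) != n_slices:
        raise ValueError(f"expected {n_slices} slice sequences, got {len(per_slice)}")
    widths = {s.shape[-1] for s in per_slice}
    if len(widths) != 1:
        raise ValueError(f"slice token widths differ: {sorted(widths)}")
    return concat(list(per_slice), axis=0)


class LQAPBlock(Module):
    """One learnable-query attention pooling stage."""

    def __init__(self, cfg: LatentPoolConfig,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cfg = cfg
        d = cfg.embed_dim
        self.queries = Tensor(xavier_uniform(rng, (cfg.n_latent, d)),
                              requires_grad=True)
        self.ln_q = LayerNorm(d)
        self.ln_k = LayerNorm(d)
        self.ln_v = LayerNorm(d)
        self.attn = MultiHeadAttention(d, cfg.heads, rng,
                                       attn_dropout=cfg.dropout)
        self.ln_mlp = LayerNorm(d)
        self.mlp = MLP(d, cfg.mlp_ratio, rng, p_dropout=cfg.dropout)
        self.p_resid = cfg.dropout

    def __call__(self, tokens: Tensor) -> Tensor:
        if not np.isfinite(tokens.data).all():
            raise ValueError("non-finite values in pooling input")
        if tokens.shape[-1] != self.cfg.embed_dim:
            raise ValueError(
                f"token width {tokens.shape[-1]} != embed dim {self.cfg.embed_dim}")
        attn_out, _ = self.attn(self.ln_q(self.queries), self.ln_k(tokens),
                                self.ln_v(tokens))
        z = dropout(attn_out, self.p_resid, self._rng, self.training) + self.queries
        z = dropout(self.mlp(self.ln_mlp(z)), self.p_resid, self._rng,
                    self.training) + z
        return z

    def expected_parameter_count(self) -> int:
        c = self.cfg
        d = c.embed_dim
        attn = 4 * (d * d + d)
        mlp = d * (c.mlp_ratio * d) + c.mlp_ratio * d + (c.mlp_ratio * d) * d + d
        return c.n_latent * d + 4 * 2 * d + attn + mlp  # 4 LayerNorms


def latent_pool_config(embed_dim: int = 768, heads: int = 12,
                       n_tokens: int = 197, dropout: float = 0.1
                       ) -> LatentPoolConfig:
    return LatentPoolConfig(n_latent=n_tokens, embed_dim=embed_dim,
                            heads=heads, dropout=dropout)


def patient_pool_config(embed_dim: int = 768, heads: int = 12,
                        dropout: float = 0.1) -> LatentPoolConfig:
    return LatentPoolConfig(n_latent=1, embed_dim=embed_dim, heads=heads,
                            dropout=dropout)


class SingleHeadAttentionPool(Module):
    """Ablation pool: one learnable query scores tokens via a key projection;
    the output is the probability-weighted mean of the *raw* tokens, so a
    zeroed query (or key projection) degrades exactly to mean pooling.
    """

    def __init__(self, embed_dim: int, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.query = Tensor(xavier_uniform(rng, (1, embed_dim)),
                            requires_grad=True)
        self.wk = Linear(embed_dim, embed_dim, rng)
        self.scale = 1.0 / np.sqrt(embed_dim)

    def __call__(self, tokens: Tensor) -> Tensor:
        keys = self.wk(tokens)                         # (T, D)
        scores = (self.query @ keys.swapaxes(-1, -2)) * self.scale
        probs = scores.softmax(axis=-1)                # (1, T)
        return (probs @ tokens).reshape(tokens.shape[-1])


def baseline_pool(tokens: Tensor, mode: str,
                  pool_module: Optional[SingleHeadAttentionPool] = None
                  ) -> Tensor:
    """Mean / max / single-head attention pooling over the token dimension."""
    if mode == "mean":
        return tokens.mean(axis=0)
    if mode == "max":
        data = tokens.data
        idx = data.argmax(axis=0)
        cols = np.arange(data.shape[1])
        return tokens[(idx, cols)]
    if mode == "single_head_attn":
        if pool_module is None:
            raise ValueError("single_head_attn requires a SingleHeadAttentionPool")
        return pool_module(tokens)
    raise ValueError(f"unknown pooling mode: {mode!r}")


class ClassifierHead(Module):
    """LN -> Linear -> GELU -> Linear producing 3 class logits
    (order Normal, SCLC, NSCLC)."""

    def __init__(self, embed_dim: int = 768, hidden: int = 256,
                 n_classes: int = 3,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.ln = LayerNorm(embed_dim)
        self.fc1 = Linear(embed_dim, hidden, rng)
        self.fc2 = Linear(hidden, n_classes, rng)

    def __call__(self, embedding: Tensor) -> Tensor:
        return self.fc2(self.fc1(self.ln(embedding)).gelu())


@dataclass
class ClassPrediction:
    logits: np.ndarray
    probabilities: np.ndarray
    predicted_class: int
    max_confidence: float

    @property
    def predicted_name(self) -> str:
        return CLASS_NAMES[self.predicted_class]


def prediction_from_logits(logits: np.ndarray) -> ClassPrediction:
    logits = np.asarray(logits, dtype=np.float64).reshape(-1)
    z = logits - logits.max()
    p = np.exp(z) / np.exp(z).sum()
    k = int(p.argmax())
    return ClassPrediction(logits=logits, probabilities=p,
                           predicted_class=k, max_confidence=float(p[k]))
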