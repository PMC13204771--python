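"""Autoregressive text decoder with cross-attention to the visual context.

GPT-2-style stack: token + learned positional embeddings, 12 blocks each of
(i) masked multi-head self-attention, (ii) cross-attention where the text
side supplies queries (layer-normalized) and the pooled visual context the
raw keys/values, and (iii) a 4x GELU MLP — all pre-norm residual sublayers —
then a final LayerNorm and a language-model head weight-tied to the token
embedding.

With the 50,257-token vocabulary, 1024 positions, width 768 and 12 blocks
the decoder carries 152,806,656 trainable parameters (152.81 M; the tied
head adds none).

The single GPT-2 special token ``<|endoftext|>`` (id 50256) serves as both
beginning- and end-of-sequence marker.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .nn import (MLP, Embedding, LayerNorm, Module, MultiHeadAttention,
                 Tensor, cross_entropy_logits, dropout, no_grad)

GPT2_VOCAB = 50_257
ENDOFTEXT = 50_256  # doubles as BOS and EOS


@dataclass(frozen=True)
class DecoderConfig:
    vocab: int = GPT2_VOCAB
    embed_dim: int = 768
    layers: int = 12
    heads: int = 12
    max_positions: int = 1024
    mlp_ratio: int = 4
    dropout: float = 0.1
    max_generate: int = 64
    bos_id: int = ENDOFTEXT
    eos_id: int = ENDOFTEXT

    def __post_init__(self):
        if self.vocab <= 0:
            raise ValueError("vocab must be positive")
        if self.max_generate > self.max_positions:
            raise ValueError("max_generate cannot exceed max_positions")


TINY_DECODER = DecoderConfig(vocab=512, embed_dim=64, layers=2, heads=2,
                             max_positions=128, max_generate=32,
                             bos_id=511, eos_id=511)


def causal_mask(t: int) -> np.ndarray:
    """Additive mask forbidding attention to future positions."""
    m = np.triu(np.full((t, t), -1e9), k=1)
    return m


class DecoderBlock(Module):
    def __init__(self, cfg: DecoderConfig, rng: np.random.Generator):
        super().__init__()
        d = cfg.embed_dim
        self.ln1 = LayerNorm(d)
        self.self_attn = MultiHeadAttention(d, cfg.heads, rng,
                                            attn_dropout=cfg.dropout)
        self.ln_cross = LayerNorm(d)
        self.cross_attn = MultiHeadAttention(d, cfg.heads, rng,
                                             attn_dropout=cfg.dropout)
        self.ln2 = LayerNorm(d)
        self.mlp = MLP(d, cfg.mlp_ratio, rng, p_dropout=cfg.dropout)
        self.p_resid = cfg.dropout

    def __call__(self, h: Tensor, context: Tensor, mask: np.ndarray
                 ) -> Tuple[Tensor, Tensor]:
        x = self.ln1(h)
        sa, _ = self.self_attn(x, x, x, mask=mask)
        h = h + dropout(sa, self.p_resid, self._rng, self.training)
        # LN on the text/query path only; keys and values are the raw context
        ca, cross_probs = self.cross_attn(self.ln_cross(h), context, context)
        h = h + dropout(ca, self.p_resid, self._rng, self.training)
        m = self.mlp(self.ln2(h))
        h = h + dropout(m, self.p_resid, self._rng, self.training)
        return h, cross_probs


class TextDecoder(Module):
    """Teacher-forced training and greedy autoregressive generation."""

    def __init__(self, cfg: DecoderConfig = DecoderConfig(),
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cfg = cfg
        self.tok_emb = Embedding(cfg.vocab, cfg.embed_dim, rng)
        self.pos_emb = Embedding(cfg.max_positions, cfg.embed_dim, rng)
        for i in range(cfg.layers):
            self.register(f"block{i}", DecoderBlock(cfg, rng))
        self.ln_final = LayerNorm(cfg.embed_dim)
        self.p_embed_drop = cfg.dropout
        # LM head shares storage with the token embedding (weight tying)

    @property
    def blocks(self) -> List[DecoderBlock]:
        return [self._modules[f"block{i}"] for i in range(self.cfg.layers)]

    @property
    def lm_head_weight(self) -> Tensor:
        return self.tok_emb.weight

    def forward(self, token_ids: np.ndarray, context: Tensor,
                collect_cross_attn: bool = False
                ) -> Tuple[Tensor, List[Tensor]]:
        """Map a token sequence + visual context to per-position vocab logits."""
        token_ids = np.asarray(token_ids, dtype=np.int64)
        if token_ids.ndim != 1:
            raise ValueError("token_ids must be a 1-D sequence")
        if token_ids.size > self.cfg.max_positions:
            raise ValueError("sequence exceeds max_positions")
        if (token_ids < 0).any() or (token_ids >= self.cfg.vocab).any():
            raise ValueError("token id out of vocabulary range")
        if context.shape[-1] != self.cfg.embed_dim:
            raise ValueError(
                f"context width {context.shape[-1]} != embed dim "
                f"{self.cfg.embed_dim}")
        t = token_ids.size
        h = self.tok_emb(token_ids) + self.pos_emb(np.arange(t))
        h = dropout(h, self.p_embed_drop, self._rng, self.training)
        mask = causal_mask(t)
        cross: List[Tensor] = []
        for blk in self.blocks:
            h, probs = blk(h, context, mask)
            if collect_cross_attn:
                cross.append(probs)
        h = self.ln_final(h)
        logits = h @ self.lm_head_weight.swapaxes(0, 1)
        return logits, cross

    def decode_teacher_forced(self, token_ids: np.ndarray, context: Tensor,
                              loss_mask: Optional[np.ndarray] = None
                              ) -> Tuple[Tensor, Tensor]:
        """Single-pass training: logits over the full sequence plus the
        next-token cross-entropy (mean over unmasked positions)."""
        token_ids = np.asarray(token_ids, dtype=np.int64)
        if token_ids.size < 2:
            raise ValueError("need at least two tokens for a next-token target")
        logits, _ = self.forward(token_ids[:-1], context)
        targets = token_ids[1:]
        mask = None if loss_mask is None else np.asarray(loss_mask)[1:]
        loss = cross_entropy_logits(logits, targets, mask=mask)
        return logits, loss

    def generate(self, context: Tensor, max_new: Optional[int] = None,
                 temperature: float = 0.0,
                 rng: Optional[np.random.Generator] = None) -> np.ndarray:
        """Autoregressive generation from BOS; greedy when temperature == 0.

        Returns generated ids excluding BOS; stops at EOS (not included) or
        after ``max_new`` tokens.
        """
        max_new = self.cfg.max_generate if max_new is None else max_new
        ids = [self.cfg.bos_id]
        out: List[int] = []
        for _ in range(max_new):
            with no_grad():
                logits, _ = self.forward(
                    np.array(ids[-self.cfg.max_positions:]), context)
            last = logits.data[-1]
            if temperature <= 0.0:
                nxt = int(last.argmax())
            else:
                z = (last - last.max()) / temperature
                p = np.exp(z) / np.exp(z).sum()
                gen = rng if rng is not None else np.random.default_rng(0)
                nxt = int(gen.choice(p.size, p=p))
            if nxt == self.cfg.eos_id:
                break
            out.append(nxt)
            ids.append(nxt)
        return np.array(out, dtype=np.int64)

    def expected_parameter_count(self) -> int:
        c = self.cfg
        d = c.embed_dim
        emb = c.vocab * d + c.max_positions * d
        attn = 4 * (d * d + d)
        mlp = d * (c.mlp_ratio * d) + c.mlp_ratio * d + (c.mlp_ratio * d) * d + d
        block = 3 * 2 * d + 2 * attn + mlp
        return emb + c.layers * block + 2 * d

    # ------------------------------------------------------------ pretrained
    def load_pretrained_lm(self, path: str) -> Dict[str, List[str]]:
        """Copy shape-matching tensors from a local NPZ checkpoint.

        Cross-attention parameters (absent from a plain language model) are
        always left at their fresh initialization.  Returns a report
        ``{"copied": [...], "fresh": [...]}`` over this decoder's parameters.
        """
        import os
        if not os.path.exists(path):
            raise FileNotFoundError(
                f"pretrained checkpoint not found at {path!r}")
        ckpt = np.load(path)
        report: Dict[str, List[str]] = {"copied": [], "fresh": []}
        for name, param in self.named_parameters():
            is_cross = ".cross_attn." in name or name.endswith("ln_cross.gamma") \
                or name.endswith("ln_cross.beta")
            if (not is_cross and name in ckpt.files
                    and ckpt[name].shape == param.data.shape):
                param.data[...] = np.asarray(ckpt[name], dtype=np.float64)
                report["copied"].append(name)
            else:
                report["fresh"].append(name)
        return report
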