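"""Per-slice vision-transformer encoder (ViT-Base/16 by default).

Each CT slice is cut into non-overlapping ``p x p`` patches, linearly
projected to the embedding width, prepended with a learnable CLS token,
summed with a learnable positional embedding, and passed through a stack of
pre-norm transformer blocks (multi-head self-attention + 4x GELU MLP, both
inside residual connections), followed by a final layer normalization.

At the default configuration (224 px input, patch 16, width 768, 12 layers,
12 heads) the encoder carries 85,798,656 trainable parameters (85.80 M).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .nn import (MLP, LayerNorm, Module, MultiHeadAttention, Tensor, concat,
                 dropout, trunc_normal)


@dataclass(frozen=True)
class EncoderConfig:
    image_size: int = 224
    patch_size: int = 16
    embed_dim: int = 768
    layers: int = 12
    heads: int = 12
    mlp_ratio: int = 4
    dropout: float = 0.1
    channels: int = 3

    def __post_init__(self):
        if self.image_size % self.patch_size:
            raise ValueError("image_size must be divisible by patch_size")
        if self.embed_dim % self.heads:
            raise ValueError("embed_dim must be divisible by heads")

    @property
    def grid(self) -> int:
        return self.image_size // self.patch_size

    @property
    def n_patches(self) -> int:
        return self.grid ** 2

    @property
    def n_tokens(self) -> int:
        return self.n_patches + 1

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.heads

    @property
    def patch_dim(self) -> int:
        return self.patch_size ** 2 * self.channels


TINY_ENCODER = EncoderConfig(image_size=32, patch_size=16, embed_dim=64,
                             layers=2, heads=2, dropout=0.1)


def patchify(image: np.ndarray, patch_size: int) -> np.ndarray:
    """Cut an (H, W, C) image into row-major flattened square patches.

    Returns an array of shape (n_patches, patch_size**2 * C).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3:
        raise ValueError("expected an (H, W, C) image")
    h, w, c = image.shape
    if h % patch_size or w % patch_size:
        raise ValueError(
            f"image sides ({h}, {w}) not divisible by patch size {patch_size}")
    gh, gw = h // patch_size, w // patch_size
    x = image.reshape(gh, patch_size, gw, patch_size, c)
    x = x.transpose(0, 2, 1, 3, 4)  # (gh, gw, p, p, c)
    return x.reshape(gh * gw, patch_size * patch_size * c)


def unpatchify(patches: np.ndarray, patch_size: int, channels: int = 3) -> np.ndarray:
    """Inverse of :func:`patchify` for square grids."""
    patches = np.asarray(patches)
    n = patches.shape[0]
    g = int(round(np.sqrt(n)))
    if g * g != n:
        raise ValueError("patch count is not a perfect square")
    x = patches.reshape(g, g, patch_size, patch_size, channels)
    x = x.transpose(0, 2, 1, 3, 4)
    return x.reshape(g * patch_size, g * patch_size, channels)


class EncoderBlock(Module):
    """Pre-norm transformer block: LN -> MHSA -> +res, LN -> MLP -> +res."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.ln1 = LayerNorm(cfg.embed_dim)
        self.attn = MultiHeadAttention(cfg.embed_dim, cfg.heads, rng,
                                       attn_dropout=cfg.dropout)
        self.ln2 = LayerNorm(cfg.embed_dim)
        self.mlp = MLP(cfg.embed_dim, cfg.mlp_ratio, rng,
                       p_dropout=cfg.dropout)
        self.p_resid = cfg.dropout

    def __call__(self, x: Tensor) -> Tuple[Tensor, Tensor]:
        h = self.ln1(x)
        attn_out, probs = self.attn(h, h, h)
        x = x + dropout(attn_out, self.p_resid, self._rng, self.training)
        m = self.mlp(self.ln2(x))
        x = x + dropout(m, self.p_resid, self._rng, self.training)
        return x, probs


class ViTEncoder(Module):
    """Slice-level encoder mapping one image to an (N+1, D) token sequence."""

    def __init__(self, cfg: EncoderConfig = EncoderConfig(),
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cfg = cfg
        from .nn.layers import Linear
        self.patch_proj = Linear(cfg.patch_dim, cfg.embed_dim, rng)
        self.cls_token = Tensor(trunc_normal(rng, (1, cfg.embed_dim)),
                                requires_grad=True)
        self.pos_embed = Tensor(trunc_normal(rng, (cfg.n_tokens, cfg.embed_dim)),
                                requires_grad=True)
        for i in range(cfg.layers):
            self.register(f"block{i}", EncoderBlock(cfg, rng))
        self.ln_final = LayerNorm(cfg.embed_dim)
        self.p_embed_drop = cfg.dropout

    @property
    def blocks(self) -> List[EncoderBlock]:
        return [self._modules[f"block{i}"] for i in range(self.cfg.layers)]

    def embed_slice(self, patches: np.ndarray) -> Tensor:
        """Project patches, prepend CLS, add positional embedding (layer 0)."""
        patches = np.asarray(patches, dtype=np.float64)
        if patches.shape != (self.cfg.n_patches, self.cfg.patch_dim):
            raise ValueError(
                f"expected ({self.cfg.n_patches}, {self.cfg.patch_dim}) patches, "
                f"got {patches.shape}")
        tok = self.patch_proj(Tensor(patches))
        z0 = concat([self.cls_token, tok], axis=0) + self.pos_embed
        return dropout(z0, self.p_embed_drop, self._rng, self.training)

    def encode_tokens(self, z: Tensor,
                      collect_attn: bool = False
                      ) -> Tuple[Tensor, List[Tensor]]:
        """Run the block stack + final LN; optionally keep attention probs."""
        attns: List[Tensor] = []
        for blk in self.blocks:
            z, probs = blk(z)
            if collect_attn:
                attns.append(probs)
        return self.ln_final(z), attns

    def encode_slice(self, image: np.ndarray,
                     collect_attn: bool = False
                     ) -> Tuple[Tensor, List[Tensor]]:
        """Full path image -> (N+1, D) contextualized tokens."""
        patches = patchify(image, self.cfg.patch_size)
        z0 = self.embed_slice(patches)
        return self.encode_tokens(z0, collect_attn=collect_attn)

    def expected_parameter_count(self) -> int:
        """Closed-form parameter total for this configuration."""
        c = self.cfg
        d = c.embed_dim
        proj = c.patch_dim * d + d
        pos = c.n_tokens * d
        cls = d
        attn = 4 * (d * d + d)
        mlp = d * (c.mlp_ratio * d) + c.mlp_ratio * d + (c.mlp_ratio * d) * d + d
        block = 2 * 2 * d + attn + mlp  # 2 LayerNorms of 2D params each
        return proj + pos + cls + c.layers * block + 2 * d
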