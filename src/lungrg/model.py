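"""Full multi-slice classification + report-generation model.

Pipeline per patient: 5 slices -> ViT encoder (shared weights across
slices) -> token concatenation (5 x (N+1) tokens) -> latent query pooling to
a fixed-length visual context -> patient query pooling to a single
embedding -> classification head; the visual context additionally feeds the
cross-attention sublayers of the text decoder.

Two profiles are provided: ``base`` is the full-size architecture
(253.13 M trainable parameters in total, before the classification head
whose hidden width is a free choice); ``tiny`` is a structurally identical
scaled-down model for CPU-speed experiments and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .decoder import DecoderConfig, TextDecoder, TINY_DECODER
from .encoder import EncoderConfig, TINY_ENCODER, ViTEncoder
from .nn import Module, Tensor, cross_entropy_logits, no_grad
from .pooling import (ClassifierHead, LatentPoolConfig, LQAPBlock,
                      concat_slices, latent_pool_config, patient_pool_config,
                      prediction_from_logits)

N_SLICES = 5


@dataclass(frozen=True)
class ModelConfig:
    profile: str = "base"
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    pool_heads: int = 12
    head_hidden: int = 256
    n_slices: int = N_SLICES
    dropout: float = 0.1

    @property
    def latent_pool(self) -> LatentPoolConfig:
        return latent_pool_config(embed_dim=self.encoder.embed_dim,
                                  heads=self.pool_heads,
                                  n_tokens=self.encoder.n_tokens,
                                  dropout=self.dropout)

    @property
    def patient_pool(self) -> LatentPoolConfig:
        return patient_pool_config(embed_dim=self.encoder.embed_dim,
                                   heads=self.pool_heads,
                                   dropout=self.dropout)


BASE_CONFIG = ModelConfig()
TINY_CONFIG = ModelConfig(profile="tiny", encoder=TINY_ENCODER,
                          decoder=TINY_DECODER, pool_heads=2, head_hidden=32)


def config_for_profile(profile: str) -> ModelConfig:
    if profile == "base":
        return BASE_CONFIG
    if profile == "tiny":
        return TINY_CONFIG
    raise ValueError(f"unknown profile {profile!r}")


class MultiSliceReportModel(Module):
    def __init__(self, cfg: ModelConfig = BASE_CONFIG,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        if cfg.encoder.embed_dim != cfg.decoder.embed_dim:
            raise ValueError("encoder and decoder must share the embed width")
        self.cfg = cfg
        self.encoder = ViTEncoder(cfg.encoder, rng)
        self.lqap_latent = LQAPBlock(cfg.latent_pool, rng)
        self.lqap_patient = LQAPBlock(cfg.patient_pool, rng)
        self.head = ClassifierHead(cfg.encoder.embed_dim, cfg.head_hidden,
                                   rng=rng)
        self.decoder = TextDecoder(cfg.decoder, rng)

    # ------------------------------------------------------------- forward
    def encode_stack(self, pixels: np.ndarray, collect_attn: bool = False
                     ) -> Tuple[Tensor, List[List[Tensor]]]:
        """Per-slice encoding + token concatenation.

        ``pixels``: (n_slices, S, S, 3) normalized float array.
        Returns the 5*(N+1)-token bank and per-slice attention stacks.
        """
        if pixels.shape[0] != self.cfg.n_slices:
            raise ValueError(
                f"expected {self.cfg.n_slices} slices, got {pixels.shape[0]}")
        per_slice, attns = [], []
        for i in range(pixels.shape[0]):
            tok, att = self.encoder.encode_slice(pixels[i],
                                                 collect_attn=collect_attn)
            per_slice.append(tok)
            attns.append(att)
        return concat_slices(per_slice, self.cfg.n_slices), attns

    def forward_visual(self, pixels: np.ndarray, collect_attn: bool = False):
        """pixels -> (visual context, patient embedding, class logits)."""
        bank, attns = self.encode_stack(pixels, collect_attn=collect_attn)
        context = self.lqap_latent(bank)
        patient = self.lqap_patient(context).reshape(
            self.cfg.encoder.embed_dim)
        logits = self.head(patient)
        return context, patient, logits, attns

    def forward_joint(self, pixels: np.ndarray, token_ids: np.ndarray,
                      label: int, lambda_report: float = 0.3,
                      loss_mask: Optional[np.ndarray] = None):
        """Joint two-task forward: returns (l_total, l_cls, l_report, logits)."""
        context, _, logits, _ = self.forward_visual(pixels)
        l_cls = cross_entropy_logits(logits.reshape(1, -1),
                                     np.array([label]))
        _, l_report = self.decoder.decode_teacher_forced(token_ids, context,
                                                         loss_mask=loss_mask)
        l_total = l_cls + lambda_report * l_report
        return l_total, l_cls, l_report, logits

    def predict(self, pixels: np.ndarray):
        with no_grad():
            _, _, logits, _ = self.forward_visual(pixels)
        return prediction_from_logits(logits.data)

    # ------------------------------------------------------------ counting
    def parameter_table(self) -> Dict[str, int]:
        """Per-component trainable parameter counts."""
        rows = {
            "Encoder": self.encoder.n_parameters(),
            "Decoder": self.decoder.n_parameters(),
            "LQAP(Latent)": self.lqap_latent.n_parameters(),
            "LQAP(Patient)": self.lqap_patient.n_parameters(),
            "Head": self.head.n_parameters(),
        }
        rows["Total"] = sum(rows.values())
        return rows
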