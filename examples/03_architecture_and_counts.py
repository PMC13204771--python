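"""Architecture arithmetic and per-component parameter accounting.

A 224 px slice at patch 16 yields 196 patches + 1 CLS = 197 tokens; five
slices concatenate to 985 tokens; latent query pooling returns a fixed
197-token visual context and patient pooling a single 768-vector.  At full
size the components count 85.80 M (encoder), 152.81 M (decoder), 7.24 M /
7.09 M (latent / patient pooling).
"""
import numpy as np

from lungrg.encoder import EncoderConfig, ViTEncoder
from lungrg.decoder import DecoderConfig, TextDecoder
from lungrg.pooling import LQAPBlock, latent_pool_config, patient_pool_config

cfg = EncoderConfig()
print(f"patches per slice: {cfg.n_patches}, tokens: {cfg.n_tokens}, "
      f"concatenated (5 slices): {5 * cfg.n_tokens}")

rng = np.random.default_rng(0)
builders = [("Encoder", lambda: ViTEncoder(cfg, rng)),
            ("LQAP(Latent)", lambda: LQAPBlock(latent_pool_config(), rng)),
            ("LQAP(Patient)", lambda: LQAPBlock(patient_pool_config(), rng)),
            ("Decoder", lambda: TextDecoder(DecoderConfig(), rng))]
for name, build in builders:  # one component at a time
    module = build()
    n = module.n_parameters()
    print(f"{name:14s} {n:>12,d}  = {n / 1e6:6.2f} M")
    del module
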