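"""Run configuration: a single validated, hashable description of a
pipeline invocation (data generation, preprocessing, model profile,
training).  Unknown keys are rejected; every tunable lives in exactly one
place.  Configs round-trip through YAML canonically.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field


class DataSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_per_class: Tuple[int, int, int] = (5, 5, 5)  # Normal, SCLC, NSCLC
    volume_depth: int = 24
    rows: int = 64
    cols: int = 64
    lesion_intensity_range: Tuple[float, float] = (10.0, 60.0)
    noise_sd: float = 25.0
    mm_per_pixel: float = 3.0


class WindowSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    width: float = 1500.0
    level: float = -600.0


class TrainSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    lambda_report: float = 0.3
    max_lr: float = 1e-4
    warmup_fraction: float = 0.3
    batch_size: int = 16
    max_epochs: int = 100
    early_stop_patience: int = 5
    amp: bool = False


class TokenizerSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_merges: int = 200


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    profile: Literal["tiny", "base"] = "tiny"
    seed: int = 0
    language: Literal["EN", "TR"] = "EN"
    run_dir: str = "runs/default"
    data: DataSection = Field(default_factory=DataSection)
    window: WindowSection = Field(default_factory=WindowSection)
    train: TrainSection = Field(default_factory=TrainSection)
    tokenizer: TokenizerSection = Field(default_factory=TokenizerSection)

    def canonical_dict(self) -> dict:
        return json.loads(self.model_dump_json())

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path: str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.canonical_dict(), fh, sort_keys=True)
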