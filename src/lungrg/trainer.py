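"""Joint two-task training: stratified patient-level splitting, the combined
loss L_total = L_cls + lambda * L_report (lambda = 0.3 by default), Adam with
a one-cycle schedule (max lr 1e-4, 30% warmup, cosine annealing), early
stopping on validation loss (patience 5) and best-checkpoint tracking.

Splitting is at the patient level — all five slices of a patient live in one
partition — with per-class allocation: test = round(n * 0.10),
val = round(n * 0.20) (round half up), remainder train.  At the emulated
cohort size (256/248/263) this yields the 77-patient test set with
per-class sizes 26/25/26.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import MultiSliceReportModel, ModelConfig
from .nn import Adam, OneCycleLR, no_grad
from .pooling import CLASS_NAMES
from .preprocess import WindowParams, build_slice_stack, filter_report, \
    normalize_for_model
from .synthetic import SyntheticPatient
from .tokenizer import ByteBPETokenizer

PARENCHYMA_TAG = {"EN": "Lung Parenchyma", "TR": "Akciğer Parankimi"}


@dataclass(frozen=True)
class TrainConfig:
    lambda_report: float = 0.3
    max_lr: float = 1e-4
    warmup_fraction: float = 0.3
    batch_size: int = 16
    max_epochs: int = 100
    early_stop_patience: int = 5
    amp: bool = False  # reserved; this engine always computes in full precision
    seed: int = 0

    def __post_init__(self):
        if self.lambda_report < 0:
            raise ValueError("lambda_report must be >= 0")
        if not 0 < self.warmup_fraction < 1:
            raise ValueError("warmup_fraction must be in (0, 1)")


# ------------------------------------------------------------------ split

def stratified_split(labels: Sequence[str],
                     fractions: Tuple[float, float, float] = (0.7, 0.2, 0.1),
                     seed: int = 0,
                     classes: Optional[Sequence[str]] = None) -> np.ndarray:
    """Per-patient partition labels ('train'/'val'/'test'), stratified by
    class with a seeded within-class permutation.  ``classes`` may name the
    expected classes; one without patients contributes nothing, with a
    warning."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    labels = np.asarray(labels)
    out = np.empty(labels.size, dtype=object)
    rng = np.random.default_rng(seed)
    if classes is None:
        classes = list(dict.fromkeys(labels))  # stable class order
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        n = idx.size
        if n == 0:
            import warnings
            warnings.warn(f"class {cls!r} has no patients")
            continue
        perm = rng.permutation(idx)
        n_test = int(np.floor(n * fractions[2] + 0.5))   # round half up
        n_val = int(np.floor(n * fractions[1] + 0.5))
        out[perm[:n_test]] = "test"
        out[perm[n_test:n_test + n_val]] = "val"
        out[perm[n_test + n_val:]] = "train"
    return out


def joint_loss(l_cls: float, l_report: float, lam: float) -> float:
    """L_total = L_cls + lambda * L_report."""
    if not (np.isfinite(l_cls) and np.isfinite(l_report)):
        raise ValueError("losses must be finite")
    return l_cls + lam * l_report


# ---------------------------------------------------------------- dataset

@dataclass
class TrainSample:
    patient_id: str
    pixels: np.ndarray          # normalized (5, S, S, 3)
    token_ids: np.ndarray
    label: int


def prepare_samples(cohort: Sequence[SyntheticPatient], cfg: ModelConfig,
                    tokenizer: ByteBPETokenizer, language: str = "EN",
                    window: WindowParams = WindowParams()
                    ) -> List[TrainSample]:
    """Preprocess a cohort into model-ready samples: windowed/resized slice
    stacks plus tokenized parenchyma sentences (BOS ... EOS)."""
    samples = []
    max_len = cfg.decoder.max_positions
    for p in cohort:
        stack = build_slice_stack(p.volume, p.slice_indices, window,
                                  size=cfg.encoder.image_size,
                                  patient_id=p.patient_id, label=p.label)
        report = p.report_en if language == "EN" else p.report_tr
        filt = filter_report(report, PARENCHYMA_TAG[language], language)
        text = " ".join(filt.sentences)
        ids = tokenizer.encode(text, add_special=True)[:max_len]
        samples.append(TrainSample(
            patient_id=p.patient_id,
            pixels=normalize_for_model(stack),
            token_ids=np.asarray(ids, dtype=np.int64),
            label=CLASS_NAMES.index(p.label)))
    return samples


def train_tokenizer(cohort: Sequence[SyntheticPatient], language: str = "EN",
                    n_merges: int = 200,
                    vocab_size: int = 512) -> ByteBPETokenizer:
    """BPE tokenizer fitted on the cohort's parenchyma sentences."""
    corpus = []
    for p in cohort:
        report = p.report_en if language == "EN" else p.report_tr
        filt = filter_report(report, PARENCHYMA_TAG[language], language)
        corpus.append(" ".join(filt.sentences))
    return ByteBPETokenizer.train(corpus, n_merges, vocab_size=vocab_size)


# ------------------------------------------------------------------ train

class EarlyStopping:
    """Stop after ``patience`` consecutive non-improving validation epochs."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.bad = 0

    def update(self, val: float) -> bool:
        """Record one epoch's validation loss; True means stop now."""
        if val < self.best:
            self.best = val
            self.bad = 0
            return False
        self.bad += 1
        return self.bad >= self.patience


@dataclass
class TrainResult:
    log: List[Dict]
    best_state: Dict[str, np.ndarray]
    best_epoch: int
    best_val_loss: float
    stopped_early: bool


def _epoch_losses(model: MultiSliceReportModel, samples: List[TrainSample],
                  lam: float) -> Dict[str, float]:
    tot = cls = rep = 0.0
    for s in samples:
        with no_grad():
            l_total, l_cls, l_report, _ = model.forward_joint(
                s.pixels, s.token_ids, s.label, lambda_report=lam)
        tot += l_total.item(); cls += l_cls.item(); rep += l_report.item()
    n = max(len(samples), 1)
    return {"total": tot / n, "cls": cls / n, "report": rep / n}


def train(model: MultiSliceReportModel, train_samples: List[TrainSample],
          val_samples: List[TrainSample], config: TrainConfig,
          log_path: Optional[str] = None) -> TrainResult:
    """Seeded joint optimization with early stopping.

    One optimizer step per mini-batch (gradients averaged over the batch);
    the validation total loss drives checkpoint selection and stopping.
    """
    if not train_samples:
        raise ValueError("empty training split")
    rng = np.random.default_rng(config.seed)
    model.set_rng(np.random.default_rng(config.seed + 1))
    opt = Adam(model.parameters(), lr=config.max_lr)
    n_batches = int(np.ceil(len(train_samples) / config.batch_size))
    sched = OneCycleLR(opt, config.max_lr,
                       total_steps=config.max_epochs * n_batches,
                       warmup_fraction=config.warmup_fraction)
    lam = config.lambda_report
    log: List[Dict] = []
    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = -1
    stopper = EarlyStopping(config.early_stop_patience)
    stopped = False
    for epoch in range(config.max_epochs):
        model.train()
        order = rng.permutation(len(train_samples))
        run_tot = 0.0
        for b in range(n_batches):
            batch = order[b * config.batch_size:(b + 1) * config.batch_size]
            opt.zero_grad()
            for j in batch:
                s = train_samples[j]
                l_total, _, _, _ = model.forward_joint(
                    s.pixels, s.token_ids, s.label, lambda_report=lam)
                (l_total * (1.0 / batch.size)).backward()
                run_tot += l_total.item() / len(train_samples)
            opt.step()
            sched.step()
        model.eval()
        val = _epoch_losses(model, val_samples, lam) if val_samples else \
            {"total": run_tot, "cls": np.nan, "report": np.nan}
        entry = {"epoch": epoch, "train_total": run_tot,
                 "val_total": val["total"], "val_cls": val["cls"],
                 "val_report": val["report"], "lr": opt.lr}
        log.append(entry)
        if log_path:
            with open(log_path, "a") as fh:
                fh.write(json.dumps(entry) + "\n")
        if val["total"] < best_val:
            best_val = val["total"]
            best_state = model.state_dict()
            best_epoch = epoch
        if stopper.update(val["total"]):
            stopped = True
            break
    return TrainResult(log=log, best_state=best_state, best_epoch=best_epoch,
                       best_val_loss=float(best_val), stopped_early=stopped)


def save_checkpoint(model: MultiSliceReportModel, path: str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())


def load_checkpoint(model: MultiSliceReportModel, path: str) -> None:
    ckpt = np.load(path)
    model.load_state_dict({k: ckpt[k] for k in ckpt.files})
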