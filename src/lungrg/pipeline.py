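"""Stage orchestration: fixtures -> preprocess -> split -> train ->
evaluate -> explain, each writing immutable artifacts plus a structured
JSONL log line (stage, seed, config hash, wall time) into one run
directory.  Stages check their prerequisites and fail with a named cause
rather than producing partial output.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .gradcam import (binarize_top_quantile, grad_cam, saliency_scores,
                      score_table, summarize_scores)
from .metrics import (caption_metrics, classification_metrics,
                      confidence_analysis, confusion_matrix, roc_auc)
from .model import MultiSliceReportModel, config_for_profile
from .pooling import CLASS_NAMES, prediction_from_logits
from .preprocess import WindowParams, scale_box
from .synthetic import CohortSpec, generate_cohort, load_cohort, save_cohort
from .tokenizer import ByteBPETokenizer
from .trainer import (TrainConfig, load_checkpoint, prepare_samples,
                      save_checkpoint, stratified_split, train,
                      train_tokenizer)

STAGES = ("fixtures", "preprocess", "split", "train", "evaluate", "explain")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _log(run_dir: Path, stage: str, cfg: RunConfig, t0: float,
         **extra) -> None:
    entry = {"stage": stage, "seed": cfg.seed,
             "config_hash": cfg.config_hash(),
             "wall_time_s": round(time.time() - t0, 3), **extra}
    with open(run_dir / "log.jsonl", "a") as fh:
        fh.write(json.dumps(entry) + "\n")


def _require(run_dir: Path, stage: str, *paths: str) -> None:
    for rel in paths:
        if not (run_dir / rel).exists():
            raise StageError(stage, f"missing upstream artifact {rel!r} "
                                    f"(run its producing stage first)")


def _cohort_spec(cfg: RunConfig) -> CohortSpec:
    d = cfg.data
    return CohortSpec(n_per_class=tuple(d.n_per_class),
                      volume_depth=d.volume_depth, rows=d.rows, cols=d.cols,
                      lesion_intensity_range=tuple(d.lesion_intensity_range),
                      noise_sd=d.noise_sd, seed=cfg.seed,
                      mm_per_pixel=d.mm_per_pixel)


def _window(cfg: RunConfig) -> WindowParams:
    return WindowParams(width=cfg.window.width, level=cfg.window.level)


def run_pipeline(cfg: RunConfig, stages: Sequence[str]) -> Path:
    """Execute the requested stages in order; returns the run directory."""
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    run_dir = Path(cfg.run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    from .config import save_config
    save_config(cfg, str(run_dir / "config.yaml"))
    for s in STAGES:  # canonical order regardless of input order
        if s in stages:
            _STAGE_FN[s](cfg, run_dir)
    return run_dir


# ------------------------------------------------------------------ stages

def stage_fixtures(cfg: RunConfig, run_dir: Path) -> None:
    t0 = time.time()
    cohort = generate_cohort(_cohort_spec(cfg))
    save_cohort(cohort, str(run_dir / "fixtures"))
    _log(run_dir, "fixtures", cfg, t0, n_patients=len(cohort))


def stage_preprocess(cfg: RunConfig, run_dir: Path) -> None:
    t0 = time.time()
    _require(run_dir, "preprocess", "fixtures/manifest.csv")
    cohort = load_cohort(str(run_dir / "fixtures"))
    mcfg = config_for_profile(cfg.profile)
    tok = train_tokenizer(cohort, language=cfg.language,
                          n_merges=cfg.tokenizer.n_merges,
                          vocab_size=mcfg.decoder.vocab)
    tok.save(str(run_dir / "tokenizer.json"))
    samples = prepare_samples(cohort, mcfg, tok, language=cfg.language,
                              window=_window(cfg))
    stats = {"n_samples": len(samples),
             "stack_shape": list(samples[0].pixels.shape) if samples else [],
             "mean_tokens": float(np.mean([s.token_ids.size
                                           for s in samples]))
             if samples else 0.0}
    (run_dir / "preprocess.json").write_text(json.dumps(stats))
    _log(run_dir, "preprocess", cfg, t0, **stats)


def stage_split(cfg: RunConfig, run_dir: Path) -> None:
    t0 = time.time()
    _require(run_dir, "split", "fixtures/manifest.csv")
    cohort = load_cohort(str(run_dir / "fixtures"))
    labels = [p.label for p in cohort]
    parts = stratified_split(labels, seed=cfg.seed)
    df = pd.DataFrame({"patient_id": [p.patient_id for p in cohort],
                       "label": labels, "partition": parts})
    df.to_csv(run_dir / "split.csv", index=False)
    _log(run_dir, "split", cfg, t0,
         sizes={k: int((parts == k).sum()) for k in ("train", "val", "test")})


def _load_split(run_dir: Path) -> Dict[str, str]:
    df = pd.read_csv(run_dir / "split.csv")
    return dict(zip(df.patient_id, df.partition))


def _build_everything(cfg: RunConfig, run_dir: Path, stage: str):
    _require(run_dir, stage, "fixtures/manifest.csv", "tokenizer.json",
             "split.csv")
    cohort = load_cohort(str(run_dir / "fixtures"))
    tok = ByteBPETokenizer.load(str(run_dir / "tokenizer.json"))
    mcfg = config_for_profile(cfg.profile)
    samples = prepare_samples(cohort, mcfg, tok, language=cfg.language,
                              window=_window(cfg))
    part = _load_split(run_dir)
    return cohort, tok, mcfg, samples, part


def stage_train(cfg: RunConfig, run_dir: Path) -> None:
    t0 = time.time()
    cohort, tok, mcfg, samples, part = _build_everything(cfg, run_dir, "train")
    tr = [s for s in samples if part[s.patient_id] == "train"]
    va = [s for s in samples if part[s.patient_id] == "val"]
    if not tr:
        raise StageError("train", "empty training split")
    model = MultiSliceReportModel(mcfg, np.random.default_rng(cfg.seed))
    tc = TrainConfig(**cfg.train.model_dump(), seed=cfg.seed)
    result = train(model, tr, va, tc,
                   log_path=str(run_dir / "train_log.jsonl"))
    model.load_state_dict(result.best_state)
    save_checkpoint(model, str(run_dir / "checkpoints" / "best.npz"))
    _log(run_dir, "train", cfg, t0, best_epoch=result.best_epoch,
         best_val_loss=result.best_val_loss,
         stopped_early=result.stopped_early, epochs_run=len(result.log))


def _restore_model(cfg: RunConfig, run_dir: Path, stage: str
                   ) -> MultiSliceReportModel:
    _require(run_dir, stage, "checkpoints/best.npz")
    mcfg = config_for_profile(cfg.profile)
    model = MultiSliceReportModel(mcfg, np.random.default_rng(cfg.seed))
    load_checkpoint(model, str(run_dir / "checkpoints" / "best.npz"))
    model.eval()
    return model


def stage_evaluate(cfg: RunConfig, run_dir: Path) -> None:
    t0 = time.time()
    cohort, tok, mcfg, samples, part = _build_everything(cfg, run_dir,
                                                         "evaluate")
    model = _restore_model(cfg, run_dir, "evaluate")
    test = [s for s in samples if part[s.patient_id] == "test"]
    if not test:
        raise StageError("evaluate", "empty test split")
    by_id = {p.patient_id: p for p in cohort}
    rows, preds, truths, probs = [], [], [], []
    cands, refs = [], []
    from .nn import no_grad
    for s in test:
        with no_grad():
            context, _, logits, _ = model.forward_visual(s.pixels)
        pred = prediction_from_logits(logits.data)
        preds.append(pred)
        truths.append(s.label)
        probs.append(pred.probabilities)
        gen = model.decoder.generate(context)
        cands.append(tok.decode(gen.tolist()))
        refs.append(tok.decode([t for t in s.token_ids.tolist()
                                if t != tok.special_id]))
        rows.append({"patient_id": s.patient_id,
                     "true": CLASS_NAMES[s.label],
                     "pred": pred.predicted_name,
                     "confidence": pred.max_confidence,
                     "generated": cands[-1]})
    pd.DataFrame(rows).to_csv(run_dir / "predictions.csv", index=False)
    with open(run_dir / "generated.jsonl", "w", encoding="utf-8") as fh:
        for r, c in zip(rows, cands):
            fh.write(json.dumps({"patient_id": r["patient_id"],
                                 "language": cfg.language, "text": c},
                                ensure_ascii=False) + "\n")
    cm = confusion_matrix(truths, [p.predicted_class for p in preds])
    bundle = {
        "confusion_matrix": cm.tolist(),
        "classification": classification_metrics(cm),
        "auc": roc_auc(truths, np.array(probs)),
        "caption": caption_metrics(cands, refs).__dict__,
        "confidence": confidence_analysis(preds, truths),
    }
    (run_dir / "metrics.json").write_text(
        json.dumps(bundle, indent=1, default=float))
    _log(run_dir, "evaluate", cfg, t0, n_test=len(test),
         accuracy=bundle["classification"]["accuracy"])


def stage_explain(cfg: RunConfig, run_dir: Path) -> None:
    t0 = time.time()
    cohort, tok, mcfg, samples, part = _build_everything(cfg, run_dir,
                                                         "explain")
    model = _restore_model(cfg, run_dir, "explain")
    by_id = {p.patient_id: p for p in cohort}
    size = mcfg.encoder.image_size
    scores = []
    for s in samples:
        if part[s.patient_id] != "test":
            continue
        p = by_id[s.patient_id]
        if p.label == "Normal":
            continue
        maps = grad_cam(model, s.pixels, s.label)
        for j, k in enumerate(p.slice_indices):
            box = p.box_for_slice(k)
            if box is None:
                continue
            sbox = scale_box(box, p.volume.shape[1:], size)
            mask, _ = binarize_top_quantile(maps[j].upsampled, 0.20)
            scores.append(saliency_scores(mask, sbox, maps[j].upsampled,
                                          label=p.label,
                                          patient_id=p.patient_id,
                                          slice_index=int(k)))
    if scores:
        score_table(scores).to_csv(run_dir / "saliency.csv", index=False)
        summarize_scores(scores).to_csv(run_dir / "saliency_summary.csv",
                                        index=False)
    _log(run_dir, "explain", cfg, t0, n_scored_slices=len(scores))


_STAGE_FN = {"fixtures": stage_fixtures, "preprocess": stage_preprocess,
             "split": stage_split, "train": stage_train,
             "evaluate": stage_evaluate, "explain": stage_explain}


def count_params(profile: str) -> pd.DataFrame:
    """Per-component trainable parameter table for a profile."""
    mcfg = config_for_profile(profile)
    model = MultiSliceReportModel(mcfg, np.random.default_rng(0))
    rows = [{"Component": k, "Trainable Parameters": v,
             "Millions": round(v / 1e6, 2)}
            for k, v in model.parameter_table().items()]
    return pd.DataFrame(rows)
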