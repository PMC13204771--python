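"""Slice-wise Grad-CAM attribution and quantitative saliency validation.

For each slice, the gradient of the target class logit with respect to the
per-head attention probability maps of the *final* encoder block is
computed.  Each head's importance weight is the spatial mean of that
gradient (alpha_k = 1/Z * sum_uv dY/dA_uv); the heads are combined as
ReLU(sum_k alpha_k A_k).  The CLS-query row of the combined map supplies one
value per image patch, which is reshaped row-major to the patch grid
(14 x 14 at the base resolution), bilinearly upsampled to the display frame
and min-max normalized per slice.

Saliency maps are validated against lesion bounding boxes by binarizing the
top activation fraction (upper 20% by default, realized as the k-th largest
value threshold with ties included) and scoring IoU, Dice and the Pointing
Game (does the single highest-activation pixel fall inside the box; ties
break on the first maximal pixel in row-major order).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from .model import MultiSliceReportModel


@dataclass
class SaliencyMap:
    raw_map: np.ndarray        # (g, g) nonnegative
    upsampled: np.ndarray      # (S, S) in [0, 1]
    class_index: int
    slice_index: int
    degenerate: bool = False   # all-zero/constant raw map


@dataclass
class SaliencyScore:
    iou: float
    dice: float
    pointing_hit: bool
    label: str = ""
    patient_id: str = ""
    slice_index: int = -1


def grad_cam(model: MultiSliceReportModel, pixels: np.ndarray,
             target_class: int, out_size: Optional[int] = None
             ) -> List[SaliencyMap]:
    """One saliency map per slice for the given class logit.

    ``pixels``: normalized (n_slices, S, S, 3) input.  Dropout is disabled
    for the gradient pass.  Returns maps in slice order.
    """
    n_classes = 3
    if not 0 <= target_class < n_classes:
        raise ValueError(f"target class {target_class} out of range")
    g = model.cfg.encoder.grid
    out_size = out_size or model.cfg.encoder.image_size
    was_training = model.training
    model.eval()
    try:
        context, _, logits, attns = model.forward_visual(pixels,
                                                         collect_attn=True)
        finals = [per_slice[-1] for per_slice in attns]  # final-block probs
        for t in finals:
            t.retain_grad()
        logits[(target_class,)].backward()
    finally:
        model.train(was_training)

    maps: List[SaliencyMap] = []
    for i, probs in enumerate(finals):
        a = probs.data                    # (heads, T, T)
        grad = probs.grad
        if grad is None:
            grad = np.zeros_like(a)
        alphas = grad.mean(axis=(1, 2))   # spatial mean over (u, v), per head
        cam = np.maximum((alphas[:, None, None] * a).sum(axis=0), 0.0)
        patch_row = cam[0, 1:]            # CLS query -> patch keys
        raw = patch_row.reshape(g, g)
        up = _sk_resize(raw, (out_size, out_size), order=1, mode="edge",
                        anti_aliasing=False, preserve_range=True)
        lo, hi = up.min(), up.max()
        degenerate = not (hi > lo)
        up = np.zeros_like(up) if degenerate else (up - lo) / (hi - lo)
        maps.append(SaliencyMap(raw_map=raw, upsampled=up,
                                class_index=target_class, slice_index=i,
                                degenerate=degenerate))
    return maps


def binarize_top_quantile(sal_map: np.ndarray, fraction: float = 0.20
                          ) -> Tuple[np.ndarray, bool]:
    """Mask of the top ``fraction`` activations (ties included).

    The threshold is the k-th largest value with k = round(fraction * N).
    A constant map has no meaningful top region: the mask is empty and the
    degenerate flag set.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    sal_map = np.asarray(sal_map, dtype=np.float64)
    flat = sal_map.ravel()
    if flat.max() == flat.min():
        return np.zeros(sal_map.shape, dtype=bool), True
    k = max(int(round(fraction * flat.size)), 1)
    thr = np.partition(flat, flat.size - k)[flat.size - k]
    return sal_map >= thr, False


def _box_mask(box: Tuple[int, int, int, int], shape: Tuple[int, int]
              ) -> np.ndarray:
    r0, c0, r1, c1 = box
    if r1 <= r0 or c1 <= c0:
        raise ValueError(f"empty box {box}")
    m = np.zeros(shape, dtype=bool)
    m[r0:r1, c0:c1] = True
    return m


def saliency_scores(mask: np.ndarray, box: Tuple[int, int, int, int],
                    sal_map: np.ndarray, **ids) -> SaliencyScore:
    """IoU, Dice and Pointing Game of a binary mask against a lesion box."""
    mask = np.asarray(mask, dtype=bool)
    bm = _box_mask(box, mask.shape)
    inter = np.logical_and(mask, bm).sum()
    union = np.logical_or(mask, bm).sum()
    iou = inter / union if union else 0.0
    denom = mask.sum() + bm.sum()
    dice = 2.0 * inter / denom if denom else 0.0
    flat_idx = int(np.asarray(sal_map).argmax())  # first max, row-major
    pr, pc = np.unravel_index(flat_idx, np.asarray(sal_map).shape)
    hit = bool(bm[pr, pc])
    return SaliencyScore(iou=float(iou), dice=float(dice), pointing_hit=hit,
                         **ids)


def dice_from_iou(iou: float) -> float:
    """Algebraic identity Dice = 2*IoU / (1 + IoU)."""
    return 2.0 * iou / (1.0 + iou)


def score_table(scores: Sequence[SaliencyScore]) -> pd.DataFrame:
    return pd.DataFrame([{"patient_id": s.patient_id, "label": s.label,
                          "slice_index": s.slice_index, "iou": s.iou,
                          "dice": s.dice, "pointing_hit": s.pointing_hit}
                         for s in scores])


def summarize_scores(scores: Sequence[SaliencyScore]) -> pd.DataFrame:
    """Per-class and overall mean +- SD of IoU/Dice plus Pointing Game
    accuracy, in the usual saliency-validation table layout."""
    df = score_table(scores)
    rows = []
    groups = [(lbl, sub) for lbl, sub in df.groupby("label")]
    groups.append(("Overall", df))
    for name, sub in groups:
        rows.append({
            "Class": name, "n (Slices)": len(sub),
            "IoU Mean": sub["iou"].mean(), "IoU SD": sub["iou"].std(ddof=1),
            "Dice Mean": sub["dice"].mean(),
            "Dice SD": sub["dice"].std(ddof=1),
            "Pointing Game Accuracy": sub["pointing_hit"].mean(),
        })
    return pd.DataFrame(rows)


def save_overlays(pixels: np.ndarray, maps: Sequence[SaliencyMap],
                  out_dir: str, patient_id: str = "patient") -> List[str]:
    """Write per-slice heat-map overlay PNGs (red channel carries saliency)."""
    from pathlib import Path
    from PIL import Image
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for m in maps:
        base = pixels[m.slice_index]
        lo, hi = base.min(), base.max()
        gray = (base - lo) / (hi - lo) if hi > lo else np.zeros_like(base)
        rgb = (gray[..., :3] * 255).astype(np.float64)
        rgb[..., 0] = np.clip(rgb[..., 0] + 120 * m.upsampled, 0, 255)
        p = out / f"{patient_id}_slice{m.slice_index}_cam.png"
        Image.fromarray(rgb.astype(np.uint8)).save(p)
        paths.append(str(p))
    return paths
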