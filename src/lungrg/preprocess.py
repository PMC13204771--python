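"""Model-side preprocessing of HU volumes and raw radiology reports.

* Lung-window display mapping (window width 1500 HU, level -600 HU by
  default): the interval [level - width/2, level + width/2] is mapped
  linearly onto [0, 255] with clamping outside and round-half-even to 8 bit.
* Five selected slices are windowed, bilinearly resized to the model
  resolution (224 px by default, no corner alignment, no antialiasing
  filter) and replicated to three channels.
* Report filtering keeps only the sentences of one tagged section (the
  "Lung Parenchyma" section in this pipeline); reports carry one
  ``Tag: sentence`` line per section.

Slice selection itself is an input: the indices come from the acquisition
protocol (radiologist-chosen on real data, generator-chosen on synthetic
data); nothing here detects lesions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage.transform import resize as _sk_resize

# channel statistics of the standard pretrained ViT backbone
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])


@dataclass(frozen=True)
class WindowParams:
    width: float = 1500.0
    level: float = -600.0

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("window width must be positive")

    @property
    def lo(self) -> float:
        return self.level - self.width / 2.0

    @property
    def hi(self) -> float:
        return self.level + self.width / 2.0


@dataclass
class SliceStack:
    """One patient's preprocessed slices: (5, S, S, 3) uint8."""

    pixels: np.ndarray
    patient_id: str
    label: Optional[str] = None

    def __post_init__(self):
        if self.pixels.ndim != 4 or self.pixels.shape[-1] != 3:
            raise ValueError("pixels must be (n_slices, H, W, 3)")


@dataclass
class FilteredReport:
    sentences: List[str]
    language: str
    section_missing: bool = False


def apply_window(volume: np.ndarray, params: WindowParams = WindowParams()
                 ) -> np.ndarray:
    """Linear HU -> 8-bit display mapping with clamping; round-half-even."""
    volume = np.asarray(volume, dtype=np.float64)
    if not np.isfinite(volume).all():
        raise ValueError("non-finite HU values")
    scaled = (volume - params.lo) / params.width * 255.0
    return np.rint(np.clip(scaled, 0.0, 255.0)).astype(np.uint8)


def resize_bilinear(image: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of a 2-D 8-bit image to (size, size), pinned dialect:
    no corner alignment, no antialiasing; output stays in [0, 255] uint8."""
    image = np.asarray(image)
    if image.shape == (size, size):
        return image.astype(np.uint8)
    out = _sk_resize(image.astype(np.float64), (size, size), order=1,
                     mode="edge", anti_aliasing=False, preserve_range=True)
    return np.rint(np.clip(out, 0.0, 255.0)).astype(np.uint8)


def build_slice_stack(volume: np.ndarray, slice_indices: Sequence[int],
                      params: WindowParams = WindowParams(),
                      size: int = 224, patient_id: str = "",
                      label: Optional[str] = None) -> SliceStack:
    """Window, resize and RGB-replicate the five selected slices."""
    volume = np.asarray(volume)
    indices = [int(i) for i in slice_indices]
    if len(indices) != 5:
        raise ValueError(f"expected 5 slice indices, got {len(indices)}")
    depth = volume.shape[0]
    for i in indices:
        if not 0 <= i < depth:
            raise IndexError(f"slice index {i} out of range for depth {depth}")
    slices = []
    for i in indices:  # cranial -> caudal order preserved
        win = apply_window(volume[i], params)
        rs = resize_bilinear(win, size)
        slices.append(np.repeat(rs[..., None], 3, axis=-1))
    return SliceStack(pixels=np.stack(slices), patient_id=patient_id,
                      label=label)


def normalize_for_model(stack: SliceStack,
                        mean: np.ndarray = IMAGENET_MEAN,
                        std: np.ndarray = IMAGENET_STD) -> np.ndarray:
    """uint8 -> float: divide by 255, then per-channel standardization."""
    x = stack.pixels.astype(np.float64) / 255.0
    return (x - mean) / std


def filter_report(report: str, section_tag: str, language: str = "EN"
                  ) -> FilteredReport:
    """Keep the sentences of one tagged section, order preserved.

    Reports are one ``Tag: sentence`` line per section; the match on
    ``section_tag`` is case-insensitive.  A missing section yields an empty,
    *flagged* result rather than a silent drop.
    """
    if not report or not report.strip():
        raise ValueError("empty report")
    wanted = section_tag.strip().lower()
    hits: List[str] = []
    for line in report.splitlines():
        if ":" not in line:
            continue
        tag, _, body = line.partition(":")
        if tag.strip().lower() == wanted:
            hits.append(body.strip())
    return FilteredReport(sentences=hits, language=language,
                          section_missing=not hits)


def scale_box(box: Tuple[int, int, int, int], src_shape: Tuple[int, int],
              dst: int) -> Tuple[int, int, int, int]:
    """Rescale a (r0, c0, r1, c1) half-open box from volume pixel
    coordinates to the resized frame, floor/ceil to preserve coverage."""
    r0, c0, r1, c1 = box
    sr, sc = dst / src_shape[0], dst / src_shape[1]
    out = (int(np.floor(r0 * sr)), int(np.floor(c0 * sc)),
           int(np.ceil(r1 * sr)), int(np.ceil(c1 * sc)))
    return (max(out[0], 0), max(out[1], 0),
            min(out[2], dst), min(out[3], dst))


# ------------------------------------------------------------------ readers

def read_nifti_volume(path: str) -> np.ndarray:
    """HU volume (depth, rows, cols) from a NIfTI file."""
    import nibabel as nib
    img = nib.load(path)
    data = np.asanyarray(img.dataobj).astype(np.float64)
    return data.T  # stored transposed by our writer convention


def read_dicom_series(paths: Sequence[str]) -> np.ndarray:
    """HU volume from a DICOM series (rescale slope/intercept applied),
    sorted by InstanceNumber."""
    import pydicom
    frames = []
    for p in paths:
        ds = pydicom.dcmread(p)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        inter = float(getattr(ds, "RescaleIntercept", 0.0))
        frames.append((int(getattr(ds, "InstanceNumber", 0)),
                       ds.pixel_array.astype(np.float64) * slope + inter))
    frames.sort(key=lambda t: t[0])
    return np.stack([f for _, f in frames])


def save_slice_previews(stack: SliceStack, out_dir: str) -> List[str]:
    """Write one PNG per slice; returns the file paths."""
    from pathlib import Path
    from PIL import Image
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, sl in enumerate(stack.pixels):
        p = out / f"{stack.patient_id or 'stack'}_slice{i}.png"
        Image.fromarray(sl).save(p)
        paths.append(str(p))
    return paths
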