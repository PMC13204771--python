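"""Seeded synthetic chest-CT cohort generator.

Emulates the statistical structure the framework assumes about its training
data: per patient a Hounsfield-unit volume, five selected axial levels, a
class label (Normal / SCLC / NSCLC), an eight-sentence bilingual radiology
report with a dedicated lung-parenchyma sentence, and per-slice lesion
bounding boxes for malignant cases.

Class-conditional lesion morphology mirrors the radiological priors of the
two carcinoma families: SCLC-like lesions are compact, smooth, high-HU blobs
near the volume centre (central/hilar analogue); NSCLC-like lesions sit in
the lateral periphery, are built from a union of offset ellipsoids
(irregular margin analogue) and carry internal intensity heterogeneity.
Normal volumes contain lung parenchyma only.  Lesions are rendered as
Gaussian-smoothed ellipsoids thresholded at half-maximum, which gives smooth
edges and a well-defined binary mask.

Slice selection follows the acquisition protocol being emulated: for
malignant patients the five levels bracket the lesion's maximal-area slice
(+-2); Normal patients get five evenly spaced depths standing in for
anatomy-defined landmark levels.

Everything is a pure function of (spec seed, label, patient index): the same
arguments always reproduce byte-identical output.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

CLASS_NAMES = ("Normal", "SCLC", "NSCLC")
HU_MIN, HU_MAX = -1024, 3071
LUNG_BG_HU = -800.0

# Eight fixed-order report sections; sentence 6 is the parenchyma sentence.
SECTIONS_EN = ("Mediastinum", "Heart", "Pulmonary vessels", "Bronchi",
               "Hilar regions", "Lung Parenchyma", "Pleura", "Thoracic wall")
SECTIONS_TR = ("Mediasten", "Kalp", "Pulmoner damarlar", "Bronşlar",
               "Hiler bölgeler", "Akciğer Parankimi", "Plevra",
               "Toraks duvarı")

_BOILERPLATE_EN = (
    "The mediastinum is in the midline with normal width.",
    "Cardiac contours and size are within normal limits.",
    "The pulmonary vascular structures are of normal caliber.",
    "Both main bronchi are patent.",
    "No pathologically enlarged hilar lymph node is observed.",
    None,  # parenchyma slot
    "No pleural effusion or thickening is detected.",
    "Thoracic wall structures are unremarkable.",
)
_BOILERPLATE_TR = (
    "Mediasten orta hatta ve genişliği normaldir.",
    "Kalp konturları ve boyutları normal sınırlardadır.",
    "Pulmoner vasküler yapılar normal kalibrededir.",
    "Her iki ana bronş açıktır.",
    "Patolojik boyutta hiler lenf nodu izlenmemiştir.",
    None,
    "Plevral efüzyon veya kalınlaşma saptanmamıştır.",
    "Toraks duvarı yapıları olağandır.",
)

_PARENCHYMA_NORMAL_EN = ("Both lung parenchyma areas are normally aerated and "
                         "no focal lesion is detected.")
_PARENCHYMA_NORMAL_TR = ("Her iki akciğer parankimi normal havalanmakta olup "
                         "fokal lezyon saptanmamıştır.")
_PARENCHYMA_MASS_EN = ("In the {location} a {size} mm {margin} solid mass "
                       "lesion is observed.")
_PARENCHYMA_MASS_TR = ("{location_tr} {size} mm boyutunda {margin_tr} solid "
                       "kitle lezyonu izlenmektedir.")


@dataclass(frozen=True)
class CohortSpec:
    """Generation parameters; defaults emulate the 767-patient study cohort
    at a reduced in-plane resolution for speed."""

    n_per_class: Tuple[int, int, int] = (256, 248, 263)  # Normal, SCLC, NSCLC
    volume_depth: int = 24
    rows: int = 64
    cols: int = 64
    lesion_intensity_range: Tuple[float, float] = (10.0, 60.0)
    noise_sd: float = 25.0
    seed: int = 0
    mm_per_pixel: float = 3.0

    def __post_init__(self):
        if min(self.n_per_class) < 0:
            raise ValueError("class counts must be nonnegative")
        if min(self.volume_depth, self.rows, self.cols) <= 0:
            raise ValueError("volume dimensions must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticPatient:
    patient_id: str
    label: str
    volume: np.ndarray                 # (depth, rows, cols) int16 HU
    slice_indices: np.ndarray          # 5 strictly increasing ints
    report_tr: str
    report_en: str
    boxes: Dict[int, Tuple[int, int, int, int]]  # slice -> (r0, c0, r1, c1)

    def box_for_slice(self, k: int) -> Optional[Tuple[int, int, int, int]]:
        return self.boxes.get(int(k))


def _patient_rng(spec: CohortSpec, label: str, index: int
                 ) -> np.random.Generator:
    cls = CLASS_NAMES.index(label)
    return np.random.default_rng(
        np.random.SeedSequence([int(spec.seed) & 0x7FFFFFFF, cls, int(index)]))


def _ellipsoid(shape, center, semi, rng=None, lumps: int = 0) -> np.ndarray:
    """Binary (an)isotropic ellipsoid, optionally with offset lumps unioned
    on for an irregular margin."""
    zz, rr, cc = np.ogrid[:shape[0], :shape[1], :shape[2]]
    def one(ctr, ax):
        return (((zz - ctr[0]) / ax[0]) ** 2 + ((rr - ctr[1]) / ax[1]) ** 2
                + ((cc - ctr[2]) / ax[2]) ** 2) <= 1.0
    mask = one(center, semi)
    for _ in range(lumps):
        off = rng.uniform(-0.7, 0.7, size=3) * np.asarray(semi)
        ax = np.maximum(np.asarray(semi) * rng.uniform(0.3, 0.7, size=3), 1.0)
        mask |= one(np.asarray(center) + off, ax)
    return mask.astype(np.float64)


def generate_patient(label: str, spec: CohortSpec, index: int
                     ) -> SyntheticPatient:
    """Render one synthetic patient; deterministic in (label, spec, index)."""
    if label not in CLASS_NAMES:
        raise ValueError(f"unknown label {label!r}")
    if index < 0:
        raise ValueError("index must be >= 0")
    d, nr, nc = spec.volume_depth, spec.rows, spec.cols
    if label != "Normal" and (d < 9 or nr < 24 or nc < 24):
        raise ValueError(
            f"volume {d}x{nr}x{nc} too small to place a lesion "
            "(need depth >= 9 and in-plane >= 24)")
    if d < 5:
        raise ValueError("volume depth must allow 5 distinct slices")

    rng = _patient_rng(spec, label, index)
    vol = np.full((d, nr, nc), LUNG_BG_HU)
    if spec.noise_sd > 0:
        vol += rng.normal(0.0, spec.noise_sd, size=vol.shape)

    boxes: Dict[int, Tuple[int, int, int, int]] = {}
    if label == "Normal":
        idx = np.unique(np.round(np.linspace(0, d - 1, 5)).astype(int))
        if idx.size != 5:
            raise ValueError("volume depth too small for 5 distinct landmarks")
        slice_indices = idx
        size_mm = margin_en = margin_tr = loc_en = loc_tr = None
    else:
        scale = min(nr, nc) / 64.0
        if label == "SCLC":
            # compact central blob
            ctr = (rng.uniform(0.40, 0.60) * d,
                   rng.uniform(0.42, 0.58) * nr,
                   rng.uniform(0.42, 0.58) * nc)
            semi = (rng.uniform(3.5, 5.0),
                    rng.uniform(6.0, 9.0) * scale,
                    rng.uniform(6.0, 9.0) * scale)
            lumps = 0
        else:
            # peripheral irregular blob with internal heterogeneity
            side = rng.choice([0, 1])
            c_col = (rng.uniform(0.12, 0.30) if side == 0
                     else rng.uniform(0.70, 0.88)) * nc
            ctr = (rng.uniform(0.40, 0.60) * d,
                   rng.uniform(0.35, 0.65) * nr,
                   c_col)
            semi = (rng.uniform(3.5, 5.0),
                    rng.uniform(5.0, 9.0) * scale,
                    rng.uniform(5.0, 9.0) * scale)
            lumps = int(rng.integers(3, 6))
        ctr = (float(np.clip(ctr[0], semi[0] + 2.5, d - semi[0] - 3.5)),
               float(np.clip(ctr[1], semi[1] + 1, nr - semi[1] - 2)),
               float(np.clip(ctr[2], semi[2] + 1, nc - semi[2] - 2)))
        solid = _ellipsoid((d, nr, nc), ctr, semi, rng=rng, lumps=lumps)
        profile = gaussian_filter(solid, sigma=1.2)
        peak = profile.max()
        if peak <= 0:
            raise ValueError("degenerate lesion profile")
        profile = profile / peak
        mask = profile >= 0.5

        lesion_hu = rng.uniform(*spec.lesion_intensity_range)
        target = np.full(vol.shape, lesion_hu)
        if label == "NSCLC":
            tex = gaussian_filter(rng.normal(0.0, 1.0, size=vol.shape), 1.5)
            target += 120.0 * tex  # heterogeneous internal intensity
        vol = vol + profile * (target - vol)

        areas = mask.sum(axis=(1, 2))
        k_star = int(areas.argmax())
        k_star = int(np.clip(k_star, 2, d - 3))
        slice_indices = np.arange(k_star - 2, k_star + 3)
        for k in slice_indices:
            sl = mask[k]
            if not sl.any():
                raise ValueError(
                    "lesion does not span the 5 selected slices; "
                    "volume too thin for the configured lesion size")
            rws, cls_ = np.nonzero(sl)
            boxes[int(k)] = (int(rws.min()), int(cls_.min()),
                             int(rws.max()) + 1, int(cls_.max()) + 1)
        r0, c0, r1, c1 = boxes[k_star]
        size_mm = int(round(max(r1 - r0, c1 - c0) * spec.mm_per_pixel))
        central = abs(ctr[2] - nc / 2) < nc / 6
        right = ctr[2] < nc / 2  # image left = patient right
        side_en = "right" if right else "left"
        side_tr = "sağ" if right else "sol"
        if label == "SCLC" or central:
            loc_en = f"central {side_en} lung, adjacent to the hilum,"
            loc_tr = f"Santral yerleşimli {side_tr} akciğerde, hilusa komşu,"
        else:
            loc_en = f"peripheral {side_en} lung"
            loc_tr = f"Periferik yerleşimli {side_tr} akciğerde"
        if label == "SCLC":
            margin_en, margin_tr = "smooth-contoured", "düzgün konturlu"
        else:
            margin_en, margin_tr = ("spiculated irregular-margined",
                                    "spiküle düzensiz konturlu")

    vol = np.clip(np.rint(vol), HU_MIN, HU_MAX).astype(np.int16)

    if label == "Normal":
        par_en, par_tr = _PARENCHYMA_NORMAL_EN, _PARENCHYMA_NORMAL_TR
    else:
        par_en = _PARENCHYMA_MASS_EN.format(location=loc_en, size=size_mm,
                                            margin=margin_en)
        par_tr = _PARENCHYMA_MASS_TR.format(location_tr=loc_tr, size=size_mm,
                                            margin_tr=margin_tr)
    report_en = "\n".join(
        f"{tag}: {(_BOILERPLATE_EN[i] if _BOILERPLATE_EN[i] else par_en)}"
        for i, tag in enumerate(SECTIONS_EN))
    report_tr = "\n".join(
        f"{tag}: {(_BOILERPLATE_TR[i] if _BOILERPLATE_TR[i] else par_tr)}"
        for i, tag in enumerate(SECTIONS_TR))

    pid = f"{label.lower()}-{index:04d}"
    return SyntheticPatient(patient_id=pid, label=label, volume=vol,
                            slice_indices=np.asarray(slice_indices, dtype=int),
                            report_tr=report_tr, report_en=report_en,
                            boxes=boxes)


def generate_cohort(spec: CohortSpec) -> List[SyntheticPatient]:
    """All patients for the spec, grouped Normal / SCLC / NSCLC."""
    cohort: List[SyntheticPatient] = []
    for label, n in zip(CLASS_NAMES, spec.n_per_class):
        for i in range(n):
            cohort.append(generate_patient(label, spec, i))
    ids = [p.patient_id for p in cohort]
    assert len(set(ids)) == len(ids)
    return cohort


# --------------------------------------------------------------------- io

def patient_digest(p: SyntheticPatient) -> str:
    h = hashlib.sha256()
    h.update(p.volume.tobytes())
    h.update(p.slice_indices.astype(np.int64).tobytes())
    h.update(p.report_tr.encode())
    h.update(p.report_en.encode())
    h.update(json.dumps({str(k): v for k, v in sorted(p.boxes.items())},
                        sort_keys=True).encode())
    return h.hexdigest()


def cohort_manifest(cohort: Sequence[SyntheticPatient]) -> List[Dict]:
    return [{"patient_id": p.patient_id, "label": p.label,
             "digest": patient_digest(p)} for p in cohort]


def manifest_hash(cohort: Sequence[SyntheticPatient]) -> str:
    h = hashlib.sha256()
    for row in cohort_manifest(cohort):
        h.update(json.dumps(row, sort_keys=True).encode())
    return h.hexdigest()


def save_cohort(cohort: Sequence[SyntheticPatient], out_dir: str,
                nifti: bool = False) -> Path:
    """NPZ volume + JSON sidecar per patient, plus a manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p in cohort:
        np.savez(out / f"{p.patient_id}.npz", volume=p.volume,
                 slice_indices=p.slice_indices)
        sidecar = {"patient_id": p.patient_id, "label": p.label,
                   "report_tr": p.report_tr, "report_en": p.report_en,
                   "boxes": {str(k): list(v) for k, v in p.boxes.items()}}
        (out / f"{p.patient_id}.json").write_text(
            json.dumps(sidecar, ensure_ascii=False, indent=1),
            encoding="utf-8")
        if nifti:
            import nibabel as nib
            img = nib.Nifti1Image(p.volume.astype(np.int16).T, np.eye(4))
            nib.save(img, str(out / f"{p.patient_id}.nii"))
    with open(out / "manifest.csv", "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["patient_id", "label", "digest"])
        w.writeheader()
        w.writerows(cohort_manifest(cohort))
    return out


def load_cohort(in_dir: str) -> List[SyntheticPatient]:
    out: List[SyntheticPatient] = []
    root = Path(in_dir)
    with open(root / "manifest.csv") as fh:
        rows = list(csv.DictReader(fh))
    for row in rows:
        pid = row["patient_id"]
        arr = np.load(root / f"{pid}.npz")
        meta = json.loads((root / f"{pid}.json").read_text(encoding="utf-8"))
        out.append(SyntheticPatient(
            patient_id=pid, label=meta["label"], volume=arr["volume"],
            slice_indices=arr["slice_indices"],
            report_tr=meta["report_tr"], report_en=meta["report_en"],
            boxes={int(k): tuple(v) for k, v in meta["boxes"].items()}))
    return out
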