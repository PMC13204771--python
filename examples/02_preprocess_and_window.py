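"""Lung-window display mapping and slice-stack assembly.

The lung window (width 1500 HU, level -600 HU) maps
[-1350, 150] HU linearly onto [0, 255]; values outside clamp.  The five
selected slices are windowed, bilinearly resized and replicated to RGB.
"""
import numpy as np

from lungrg.preprocess import (WindowParams, apply_window, build_slice_stack,
                               filter_report)
from lungrg.synthetic import CohortSpec, generate_patient

w = WindowParams()  # width 1500, level -600
for hu in (-1350, -600, 150, -1024, 500):
    print(f"HU {hu:6d} -> display {apply_window(np.array([hu]), w)[0]:3d}")

p = generate_patient("NSCLC", CohortSpec(n_per_class=(0, 0, 1), seed=7), 0)
stack = build_slice_stack(p.volume, p.slice_indices, w, size=224,
                          patient_id=p.patient_id, label=p.label)
print(f"\nslice stack: {stack.pixels.shape} dtype={stack.pixels.dtype} "
      f"(5 slices x 224 x 224 x RGB)")

filt = filter_report(p.report_en, "Lung Parenchyma")
print(f"\nparenchyma-only report ({len(filt.sentences)} sentence):")
print(" ", filt.sentences[0])
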