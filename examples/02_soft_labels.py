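"""Soft-label weight maps from a binary annotation.

Erosion and dilation of an annotation mask define a certain core, an
uncertain boundary band, and background; the per-pixel loss weights are
2 / 1.5 / 1 respectively.
"""

import numpy as np

from dslfcn import AnnotationSet, decompose_regions, weight_map_for_annotations

mask = np.zeros((11, 11), dtype=bool)
mask[3:8, 3:8] = True  # a 5x5 annotated square
ann = AnnotationSet.from_masks([mask])

footprint = np.ones((3, 3), dtype=bool)
decomp = decompose_regions(ann, footprint)
print(f"annotation {mask.sum()} px -> core {decomp.core[0].sum()} px, "
      f"soft band {decomp.soft[0].sum()} px")

wm = weight_map_for_annotations(ann, footprint)
for value, name in [(2.0, "core"), (1.5, "boundary band"), (1.0, "background")]:
    print(f"omega = {value:>4}: {(wm.omega == value).sum():3d} px  ({name})")
print(wm.omega)

# Training then pays double attention to the certain interior, 1.5x to the
# uncertain rim where annotators disagree, and baseline weight elsewhere.
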