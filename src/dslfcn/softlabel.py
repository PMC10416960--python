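"""Morphology-derived soft labels: core / boundary-band / background weights.

Manual annotations of nuclei and hybridization signals are least reliable at
the object boundary.  Each binary annotation mask is eroded and dilated with
a small structuring element; the pixels gained or lost form a *soft band*
around the drawn contour.  The per-pixel loss weight is then

* ``core_weight``  (default 2.0)  inside the eroded core,
* ``band_weight``  (default 1.5)  in the soft band,
* ``background_weight`` (default 1.0) elsewhere,

so training pays most attention to the certain interior, less to the
uncertain rim, and least to background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from PIL import Image
from scipy import ndimage as ndi
from skimage.morphology import disk

__all__ = [
    "AnnotationSet",
    "RegionDecomposition",
    "WeightMap",
    "decompose_regions",
    "build_weight_map",
    "hard_label_from_annotations",
    "weight_map_for_annotations",
    "read_mask_png",
    "write_weight_map",
]

DEFAULT_FOOTPRINT_RADIUS = 3
DEFAULT_CORE_WEIGHT = 2.0
DEFAULT_BAND_WEIGHT = 1.5
DEFAULT_BACKGROUND_WEIGHT = 1.0


@dataclass(frozen=True)
class AnnotationSet:
    """A set of per-object binary masks sharing one image frame."""

    masks: tuple[np.ndarray, ...]
    image_shape: tuple[int, int]

    @classmethod
    def from_masks(cls, masks: Sequence[np.ndarray], image_shape: tuple[int, int] | None = None) -> "AnnotationSet":
        masks = tuple(np.asarray(m).astype(bool) for m in masks)
        if image_shape is None:
            if not masks:
                raise ValueError("image_shape required when the annotation list is empty")
            image_shape = masks[0].shape
        for m in masks:
            if m.shape != tuple(image_shape):
                raise ValueError(f"mask shape {m.shape} != image shape {image_shape}")
        return cls(masks, tuple(image_shape))

    def __len__(self) -> int:
        return len(self.masks)

    def union(self) -> np.ndarray:
        out = np.zeros(self.image_shape, dtype=bool)
        for m in self.masks:
            out |= m
        return out


@dataclass(frozen=True)
class RegionDecomposition:
    """Per-annotation core/band decomposition.

    For each original region ``r_a``: ``core = erosion(r_a)``,
    ``outer = dilation(r_a)``, the erosion band is ``r_a & ~core``, the
    dilation band ``outer & ~r_a``, and the soft region their union.
    """

    original: tuple[np.ndarray, ...]
    core: tuple[np.ndarray, ...]
    outer: tuple[np.ndarray, ...]
    erosion_band: tuple[np.ndarray, ...]
    dilation_band: tuple[np.ndarray, ...]
    soft: tuple[np.ndarray, ...]
    footprint: np.ndarray
    image_shape: tuple[int, int]

    def core_union(self) -> np.ndarray:
        return _union(self.core, self.image_shape)

    def soft_union(self) -> np.ndarray:
        return _union(self.soft, self.image_shape)


@dataclass(frozen=True)
class WeightMap:
    """Per-pixel loss weights taking one of three values."""

    omega: np.ndarray
    core_weight: float = DEFAULT_CORE_WEIGHT
    band_weight: float = DEFAULT_BAND_WEIGHT
    background_weight: float = DEFAULT_BACKGROUND_WEIGHT


def _union(masks: Sequence[np.ndarray], shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    for m in masks:
        out |= m
    return out


def decompose_regions(annotations: AnnotationSet, footprint: np.ndarray | None = None) -> RegionDecomposition:
    """Erode/dilate every annotation mask and split it into core and bands.

    Morphology pads with background (zeros) at the image border, the
    standard convention; an annotation smaller than the footprint simply
    yields an empty core.
    """
    if footprint is None:
        footprint = disk(DEFAULT_FOOTPRINT_RADIUS)
    footprint = np.asarray(footprint).astype(bool)
    if not footprint.any():
        raise ValueError("structuring element must be non-empty")
    core, outer, ero_band, dil_band, soft = [], [], [], [], []
    for m in annotations.masks:
        c = ndi.binary_erosion(m, structure=footprint, border_value=0)
        o = ndi.binary_dilation(m, structure=footprint, border_value=0)
        e = m & ~c
        d = o & ~m
        core.append(c)
        outer.append(o)
        ero_band.append(e)
        dil_band.append(d)
        soft.append(e | d)
    return RegionDecomposition(
        original=annotations.masks,
        core=tuple(core),
        outer=tuple(outer),
        erosion_band=tuple(ero_band),
        dilation_band=tuple(dil_band),
        soft=tuple(soft),
        footprint=footprint,
        image_shape=annotations.image_shape,
    )


def build_weight_map(
    decomp: RegionDecomposition,
    core_weight: float = DEFAULT_CORE_WEIGHT,
    band_weight: float = DEFAULT_BAND_WEIGHT,
    background_weight: float = DEFAULT_BACKGROUND_WEIGHT,
) -> WeightMap:
    """Assemble the three-valued weight image from a region decomposition.

    Where annotations overlap, the strongest region wins: core beats the
    soft band beats background.
    """
    if min(core_weight, band_weight, background_weight) <= 0:
        raise ValueError("weights must be positive")
    omega = np.full(decomp.image_shape, background_weight, dtype=np.float32)
    omega[decomp.soft_union()] = band_weight
    omega[decomp.core_union()] = core_weight
    return WeightMap(omega, core_weight, band_weight, background_weight)


def weight_map_for_annotations(
    annotations: AnnotationSet,
    footprint: np.ndarray | None = None,
    core_weight: float = DEFAULT_CORE_WEIGHT,
    band_weight: float = DEFAULT_BAND_WEIGHT,
    background_weight: float = DEFAULT_BACKGROUND_WEIGHT,
) -> WeightMap:
    """Convenience: decompose and weight in one call."""
    return build_weight_map(decompose_regions(annotations, footprint), core_weight, band_weight, background_weight)


def hard_label_from_annotations(annotations: AnnotationSet, class_id: int = 1) -> np.ndarray:
    """Rasterize the union of annotation masks to a hard label image.

    Pixels under any mask get ``class_id``; everything else is background 0.
    """
    if class_id < 1:
        raise ValueError("class_id must be >= 1 (0 is background)")
    label = np.zeros(annotations.image_shape, dtype=np.int64)
    label[annotations.union()] = class_id
    return label


def read_mask_png(path) -> np.ndarray:
    """Read a single-channel PNG mask, binarized at intensity > 127."""
    arr = np.asarray(Image.open(path).convert("L"))
    return arr > 127


def write_weight_map(wm: WeightMap, tiff_path=None, preview_png_path=None) -> None:
    """Write the weight map as float32 TIFF and/or an 8-bit preview PNG
    (core -> 255, band -> 170, background -> 85)."""
    if tiff_path is not None:
        import tifffile

        tifffile.imwrite(str(tiff_path), wm.omega.astype(np.float32))
    if preview_png_path is not None:
        prev = np.full(wm.omega.shape, 85, dtype=np.uint8)
        prev[wm.omega == wm.band_weight] = 170
        prev[wm.omega == wm.core_weight] = 255
        Image.fromarray(prev).save(str(preview_png_path))
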