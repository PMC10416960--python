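"""Gigapixel slide processing: tile addressing, background filtering, stitching.

A whole-slide image (WSI) is far too large to segment in one pass, so it is
restructured as a grid of fixed-size tiles.  A pixel at slide coordinates
``(a, b)`` (a = x/column, b = y/row, 0-based) lives in tile
``(w, psi) = (a // alpha, b // beta)`` at tile-local offset
``(i, j) = (a - w*alpha, b - psi*beta)``; the decomposition is exactly
invertible.  Background tiles are removed cheaply before any model runs: a
global Otsu threshold on a slide thumbnail (taken at the pyramid level whose
extent is closest to a single tile) classifies pixels into tissue and
background, and only tiles with more than a configurable tissue fraction
(default 0.70; tiles at or below it are discarded) reach the network.  Kept
tiles are segmented one by one, the per-pixel argmax class map is reduced to
the target class (class indices above 1), and the tile results are stitched
back into slide coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .loss import softmax_probs

logger = logging.getLogger(__name__)

__all__ = [
    "TileIndex",
    "TileGrid",
    "SlideHandle",
    "tile_index",
    "foreground_filter",
    "predict_tile",
    "class_map",
    "extract_target",
    "run_slide",
    "stitch_tiles",
    "TargetMask",
    "SlideResult",
]

DEFAULT_TILE = 512
DEFAULT_FG_THRESHOLD = 0.70


# ---------------------------------------------------------------------------
# addressing


@dataclass(frozen=True)
class TileIndex:
    """Tile (w, psi) and in-tile (i, j) address of one slide pixel at level ``level``."""

    w: int
    psi: int
    i: int
    j: int
    level: int = 0


def tile_index(a: int, b: int, alpha: int = DEFAULT_TILE, beta: int = DEFAULT_TILE, level: int = 0) -> TileIndex:
    """Floor/remainder decomposition of slide coordinates into a tile address.

    Inverse mapping: ``a = w * alpha + i``, ``b = psi * beta + j``.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("tile dimensions must be positive")
    if a < 0 or b < 0:
        raise ValueError(f"coordinates must be non-negative, got ({a}, {b})")
    w, psi = a // alpha, b // beta
    return TileIndex(int(w), int(psi), int(a - w * alpha), int(b - psi * beta), level)


@dataclass(frozen=True)
class TileGrid:
    """Tile counts covering a slide of (a_max, b_max) pixels."""

    a_max: int
    b_max: int
    alpha: int = DEFAULT_TILE
    beta: int = DEFAULT_TILE

    @property
    def n_cols(self) -> int:  # zeta
        return -(-self.a_max // self.alpha)

    @property
    def n_rows(self) -> int:  # eta
        return -(-self.b_max // self.beta)

    def __len__(self) -> int:
        return self.n_cols * self.n_rows

    def index(self, a: int, b: int) -> TileIndex:
        if not (0 <= a < self.a_max and 0 <= b < self.b_max):
            raise ValueError(f"({a}, {b}) outside slide ({self.a_max}, {self.b_max})")
        return tile_index(a, b, self.alpha, self.beta)

    def tiles(self) -> Iterator[tuple[int, int]]:
        """Row-major tile order: fixed, so reports are reproducible."""
        for psi in range(self.n_rows):
            for w in range(self.n_cols):
                yield w, psi


# ---------------------------------------------------------------------------
# slide container


class SlideHandle:
    """A slide held as a level-0 array plus a 2x-downsampled pyramid.

    Accepts any (H, W, 3) array (flat TIFF and PNG mosaics read fine with
    tifffile/Pillow); the pyramid is built by 2x2 block averaging until both
    extents drop to or below the tile size.
    """

    def __init__(self, image: np.ndarray, alpha: int = DEFAULT_TILE, beta: int = DEFAULT_TILE):
        image = np.asarray(image)
        if image.ndim == 2:
            image = np.stack([image] * 3, axis=-1)
        if image.ndim != 3 or image.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) image, got {image.shape}")
        if image.dtype == np.uint8:
            image = image.astype(np.float32) / 255.0
        self.alpha, self.beta = alpha, beta
        self.levels = [image.astype(np.float32)]
        while max(self.levels[-1].shape[:2]) > max(alpha, beta):
            self.levels.append(_downsample2(self.levels[-1]))

    @classmethod
    def from_path(cls, path, alpha: int = DEFAULT_TILE, beta: int = DEFAULT_TILE) -> "SlideHandle":
        p = str(path)
        if p.lower().endswith((".tif", ".tiff")):
            import tifffile

            arr = tifffile.imread(p)
        else:
            from PIL import Image

            arr = np.asarray(Image.open(p).convert("RGB"))
        return cls(arr, alpha, beta)

    @property
    def b_max(self) -> int:  # rows
        return self.levels[0].shape[0]

    @property
    def a_max(self) -> int:  # cols
        return self.levels[0].shape[1]

    @property
    def grid(self) -> TileGrid:
        return TileGrid(self.a_max, self.b_max, self.alpha, self.beta)

    def tile(self, w: int, psi: int, pad: bool = False) -> np.ndarray:
        """Level-0 tile (w, psi); ``pad`` zero-pads edge tiles to (beta, alpha)."""
        t = self.levels[0][psi * self.beta : (psi + 1) * self.beta, w * self.alpha : (w + 1) * self.alpha]
        if pad and t.shape[:2] != (self.beta, self.alpha):
            t = np.pad(t, ((0, self.beta - t.shape[0]), (0, self.alpha - t.shape[1]), (0, 0)))
        return t

    def thumbnail_level(self) -> int:
        """Pyramid level whose extent is closest to a single unit tile."""
        target = max(self.alpha, self.beta)
        diffs = [abs(max(lv.shape[:2]) - target) for lv in self.levels]
        return int(np.argmin(diffs))


def _downsample2(img: np.ndarray) -> np.ndarray:
    h, w = img.shape[:2]
    if h % 2 or w % 2:
        img = np.pad(img, ((0, h % 2), (0, w % 2), (0, 0)), mode="edge")
        h, w = img.shape[:2]
    return img.reshape(h // 2, 2, w // 2, 2, img.shape[2]).mean(axis=(1, 3))


def _luminance(rgb: np.ndarray) -> np.ndarray:
    if rgb.ndim == 2:
        return rgb
    return rgb @ np.array([0.2126, 0.7152, 0.0722], dtype=rgb.dtype)


# ---------------------------------------------------------------------------
# background filtering


def foreground_filter(
    thumbnail: np.ndarray,
    threshold_fraction: float = DEFAULT_FG_THRESHOLD,
    field: str = "bright",
    otsu_threshold: float | None = None,
) -> tuple[bool, float]:
    """Tissue fraction of a (tile) thumbnail and the keep/discard decision.

    ``otsu_threshold`` is normally the global threshold computed on the
    whole-slide thumbnail; if omitted it is computed from the given image.
    Tissue is the darker Otsu class on bright-field slides and the brighter
    class on dark-field (FISH-like) slides.  A tile is kept only when its
    tissue fraction strictly exceeds ``threshold_fraction``; a
    uniform-intensity thumbnail (Otsu undefined) counts as all background.
    """
    if field not in ("bright", "dark"):
        raise ValueError("field must be 'bright' or 'dark'")
    gray = _luminance(np.asarray(thumbnail, dtype=np.float64))
    if otsu_threshold is None:
        if np.ptp(gray) == 0:
            return False, 0.0
        from skimage.filters import threshold_otsu

        otsu_threshold = float(threshold_otsu(gray))
    tissue = gray < otsu_threshold if field == "bright" else gray > otsu_threshold
    r = float(tissue.mean())
    return r > threshold_fraction, r


# ---------------------------------------------------------------------------
# per-tile inference


def predict_tile(model, tile: np.ndarray) -> np.ndarray:
    """Per-pixel, per-class softmax probabilities for one (beta, alpha, 3) tile."""
    tile = np.asarray(tile)
    if tile.ndim != 3 or tile.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) tile, got {tile.shape}")
    return softmax_probs(model.predict_scores(tile))


def class_map(probs: np.ndarray) -> np.ndarray:
    """Per-pixel argmax class; ties resolve to the lowest class index."""
    return np.asarray(probs).argmax(axis=0)


@dataclass(frozen=True)
class TargetMask:
    """Image content retained where the class map exceeds 1 (the target class)."""

    content: np.ndarray  # image values where mask, 0 elsewhere
    mask: np.ndarray  # bool


def extract_target(s: np.ndarray, image: np.ndarray) -> TargetMask:
    """Suppress background and foreground, keeping pixels with class > 1."""
    s = np.asarray(s)
    image = np.asarray(image)
    if s.shape != image.shape[: s.ndim]:
        raise ValueError(f"class map shape {s.shape} does not match image {image.shape}")
    mask = s > 1
    content = np.where(mask[..., None] if image.ndim == 3 else mask, image, 0)
    return TargetMask(content, mask)


# ---------------------------------------------------------------------------
# whole-slide run


@dataclass
class SlideResult:
    target_mask: np.ndarray  # (b_max, a_max) bool, stitched
    class_map: np.ndarray  # (b_max, a_max) int, stitched (discarded tiles = 0)
    report: pd.DataFrame  # tile_col, tile_row, tissue_fraction, kept, target_pixels, failed
    metadata: dict = field(default_factory=dict)


def run_slide(
    model,
    slide: SlideHandle,
    threshold_fraction: float = DEFAULT_FG_THRESHOLD,
    field: str = "bright",
) -> SlideResult:
    """Filter, segment and stitch every tile of a slide.

    The global Otsu threshold comes from the slide thumbnail at the pyramid
    level closest to one unit tile; each tile's tissue fraction is measured
    on its footprint in that thumbnail.  Kept tiles run through the model
    (edge tiles zero-padded to full size, cropped on stitch); discarded
    tiles are written as background.  A tile that raises during inference is
    logged, marked failed, and left as background.
    """
    grid = slide.grid
    lvl = slide.thumbnail_level()
    thumb = _luminance(slide.levels[lvl].astype(np.float64))
    if np.ptp(thumb) == 0:
        otsu = None  # uniform slide: everything is background
    else:
        from skimage.filters import threshold_otsu

        otsu = float(threshold_otsu(thumb))
    scale_y = thumb.shape[0] / slide.b_max
    scale_x = thumb.shape[1] / slide.a_max

    cmap = np.zeros((slide.b_max, slide.a_max), dtype=np.int64)
    rows = []
    for w, psi in grid.tiles():
        y0, y1 = psi * slide.beta, min((psi + 1) * slide.beta, slide.b_max)
        x0, x1 = w * slide.alpha, min((w + 1) * slide.alpha, slide.a_max)
        if otsu is None:
            kept, frac = False, 0.0
        else:
            ty0, ty1 = int(y0 * scale_y), max(int(y0 * scale_y) + 1, int(np.ceil(y1 * scale_y)))
            tx0, tx1 = int(x0 * scale_x), max(int(x0 * scale_x) + 1, int(np.ceil(x1 * scale_x)))
            kept, frac = foreground_filter(
                thumb[ty0:ty1, tx0:tx1], threshold_fraction, field, otsu_threshold=otsu
            )
        n_target, failed = 0, False
        if kept:
            try:
                probs = predict_tile(model, slide.tile(w, psi, pad=True))
                s = class_map(probs)[: y1 - y0, : x1 - x0]
                cmap[y0:y1, x0:x1] = s
                n_target = int((s > 1).sum())
            except Exception:
                logger.exception("tile (%d, %d) failed; leaving as background", w, psi)
                failed = True
        rows.append(
            {
                "tile_col": w,
                "tile_row": psi,
                "tissue_fraction": frac,
                "kept": kept,
                "target_pixels": n_target,
                "failed": failed,
            }
        )
    report = pd.DataFrame(rows)
    meta = {
        "tile_size": [slide.alpha, slide.beta],
        "grid": [grid.n_cols, grid.n_rows],
        "threshold_fraction": threshold_fraction,
        "field": field,
        "otsu_threshold": otsu,
        "thumbnail_level": lvl,
        "n_kept": int(report.kept.sum()),
        "n_discarded": int((~report.kept).sum()),
        "n_failed": int(report.failed.sum()),
    }
    return SlideResult(cmap > 1, cmap, report, meta)


def stitch_tiles(tiles: dict[tuple[int, int], np.ndarray], slide_shape: tuple[int, int], alpha=DEFAULT_TILE, beta=DEFAULT_TILE) -> np.ndarray:
    """Reassemble per-tile arrays into slide coordinates (inverse of tiling)."""
    sample = next(iter(tiles.values()))
    out_shape = slide_shape + sample.shape[2:]
    out = np.zeros(out_shape, dtype=sample.dtype)
    for (w, psi), t in tiles.items():
        y0, x0 = psi * beta, w * alpha
        h = min(t.shape[0], slide_shape[0] - y0)
        wd = min(t.shape[1], slide_shape[1] - x0)
        out[y0 : y0 + h, x0 : x0 + wd] = t[:h, :wd]
    return out
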