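"""Seeded synthetic microscopy fixtures.

Two regimes mirror the data the segmentation method targets:

* **FISH/DISH-like tiles** — dark-field images with elliptical "nuclei"
  (class 1, DAPI-blue) containing punctate bright "signal" dots (class 2,
  orange), over a near-black background (class 0) with mild vignetting and
  Gaussian sensor noise.  Dot-in-nucleus structure is what makes the
  three-class background/foreground/target decomposition meaningful.
* **Bright-field blob mosaics** — tile-aligned mosaics in which a known set
  of tiles is pure white background and the rest carry pinkish tissue
  texture with irregular dark-purple target blobs, for exercising the
  tile-index / foreground-filter / stitch pipeline with an exact truth
  table.

Every generator is a pure function of its configuration (including the
seed); no real slide data is emulated beyond these geometric and intensity
conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .softlabel import AnnotationSet

__all__ = [
    "FixtureConfig",
    "FishTile",
    "BlobMosaic",
    "PlacementError",
    "make_fish_like_tile",
    "make_blob_mosaic",
    "perturb_annotations",
]


class PlacementError(RuntimeError):
    """Raised when the requested objects cannot be placed without overlap."""


@dataclass(frozen=True)
class FixtureConfig:
    """Generator settings; identical config + seed gives bitwise-identical output."""

    seed: int = 0
    image_size: int = 256
    n_objects: int = 5
    boundary_jitter: float = 0.0
    background: str = "dark"  # dark (FISH-like) | bright (H&E-like)
    blank_tile_fraction: float = 0.0  # mosaics only
    tile_size: int = 512  # mosaics only
    noise_sigma: float = 5.0 / 255.0
    dots_per_nucleus: tuple[int, int] = (2, 6)
    nucleus_radius: tuple[float, float] = (0.07, 0.12)  # fraction of image size
    dot_radius: tuple[float, float] = (2.0, 4.0)  # pixels


@dataclass(frozen=True)
class FishTile:
    image: np.ndarray  # (H, W, 3) float32 in [0, 1]
    nuclei: AnnotationSet
    signals: AnnotationSet
    label: np.ndarray  # (H, W) int64 in {0, 1, 2}


@dataclass(frozen=True)
class BlobMosaic:
    image: np.ndarray  # (H, W, 3) float32 in [0, 1]
    truth: pd.DataFrame  # columns: tile_col, tile_row, tissue_fraction, blank
    target_mask: np.ndarray  # (H, W) bool — target blobs


def _ellipse_mask(shape, cy, cx, ry, rx, angle, yy, xx):
    ca, sa = np.cos(angle), np.sin(angle)
    y, x = yy - cy, xx - cx
    u = (ca * x + sa * y) / rx
    v = (-sa * x + ca * y) / ry
    return u * u + v * v <= 1.0


def _disk_mask(shape, cy, cx, r, yy, xx):
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def make_fish_like_tile(config: FixtureConfig) -> FishTile:
    """Dark-field tile with non-overlapping elliptical nuclei and in-nucleus dots.

    Raises :class:`PlacementError` when ``n_objects`` nuclei cannot be placed
    without overlap within a bounded number of retries.
    """
    if config.background != "dark":
        raise ValueError("FISH-like tiles use a dark background")
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)

    nuclei: list[np.ndarray] = []
    occupied = np.zeros((size, size), dtype=bool)
    r_lo, r_hi = (r * size for r in config.nucleus_radius)
    for _ in range(config.n_objects):
        placed = False
        for _attempt in range(200):
            ry, rx = rng.uniform(r_lo, r_hi, 2)
            margin = max(ry, rx) + 2
            cy = rng.uniform(margin, size - margin)
            cx = rng.uniform(margin, size - margin)
            m = _ellipse_mask((size, size), cy, cx, ry, rx, rng.uniform(0, np.pi), yy, xx)
            grown = ndi.binary_dilation(m, iterations=3)
            if not (grown & occupied).any():
                nuclei.append(m)
                occupied |= grown
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place {config.n_objects} nuclei of radius ~{r_hi:.0f}px in a {size}px tile"
            )

    dots: list[np.ndarray] = []
    for m in nuclei:
        eroded = ndi.binary_erosion(m, iterations=4)
        ys, xs = np.nonzero(eroded if eroded.any() else m)
        n_dots = rng.integers(config.dots_per_nucleus[0], config.dots_per_nucleus[1] + 1)
        for _ in range(n_dots):
            k = rng.integers(len(ys))
            r = rng.uniform(*config.dot_radius)
            dots.append(_disk_mask((size, size), ys[k], xs[k], r, yy, xx))

    nuclei_u = np.zeros((size, size), dtype=bool)
    for m in nuclei:
        nuclei_u |= m
    dots_u = np.zeros((size, size), dtype=bool)
    for m in dots:
        dots_u |= m
    dots_u &= nuclei_u  # targets live inside objects by construction

    label = np.zeros((size, size), dtype=np.int64)
    label[nuclei_u] = 1
    label[dots_u] = 2

    # render: vignetted dark background, blue-ish nuclei, bright orange dots
    img = np.zeros((size, size, 3), dtype=np.float64)
    rad = np.hypot(yy - size / 2, xx - size / 2) / (size / 2)
    vignette = 1.0 - 0.35 * rad**2
    img += 0.03 * vignette[..., None]
    nucleus_intensity = ndi.gaussian_filter(rng.uniform(0.6, 1.0, (size, size)), 4)
    for c, w in enumerate((0.12, 0.25, 0.80)):
        img[..., c][nuclei_u] = (w * nucleus_intensity * vignette)[nuclei_u]
    for c, w in enumerate((0.95, 0.45, 0.10)):
        img[..., c][dots_u] = w
    img += rng.normal(0.0, config.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    return FishTile(
        image=img,
        nuclei=AnnotationSet.from_masks(nuclei, (size, size)),
        signals=AnnotationSet.from_masks([d & nuclei_u for d in dots], (size, size)),
        label=label,
    )


def _blob(shape, cy, cx, r_mean, rng, yy, xx):
    """Irregular blob: disk warped by a low-frequency radial perturbation."""
    theta = np.arctan2(yy - cy, xx - cx)
    n_harm = 4
    amps = rng.uniform(0.0, 0.35, n_harm) * r_mean
    phases = rng.uniform(0, 2 * np.pi, n_harm)
    r = r_mean + sum(a * np.cos((k + 2) * theta + p) for k, (a, p) in enumerate(zip(amps, phases)))
    return np.hypot(yy - cy, xx - cx) <= r


def make_blob_mosaic(config: FixtureConfig) -> BlobMosaic:
    """Bright-field tile mosaic with an exact per-tile truth table.

    ``image_size`` must be a multiple of ``tile_size``; exactly
    ``round(blank_tile_fraction * n_tiles)`` tiles (seeded choice) are pure
    background, the rest are fully covered by tissue texture containing
    irregular dark target blobs.
    """
    if config.image_size % config.tile_size:
        raise ValueError("mosaic image_size must be a multiple of tile_size")
    rng = np.random.default_rng(config.seed)
    size, ts = config.image_size, config.tile_size
    n = size // ts
    n_tiles = n * n
    n_blank = int(round(config.blank_tile_fraction * n_tiles))
    blank_idx = rng.choice(n_tiles, size=n_blank, replace=False)
    blank = np.zeros(n_tiles, dtype=bool)
    blank[blank_idx] = True

    img = np.full((size, size, 3), 0.96, dtype=np.float64)
    target = np.zeros((size, size), dtype=bool)
    rows = []
    tile_yy, tile_xx = np.mgrid[0:ts, 0:ts].astype(np.float64)
    for psi in range(n):
        for w in range(n):
            idx = psi * n + w
            sl = (slice(psi * ts, (psi + 1) * ts), slice(w * ts, (w + 1) * ts))
            if not blank[idx]:
                texture = ndi.gaussian_filter(rng.standard_normal((ts, ts)), 6)
                texture = 0.10 * texture / max(np.abs(texture).max(), 1e-9)
                for c, base in enumerate((0.80, 0.55, 0.72)):
                    img[sl][..., c] = np.clip(base + texture, 0, 1)
                for _ in range(config.n_objects):
                    # metastasis-like deposits are large relative to a tile
                    r = rng.uniform(0.12, 0.26) * ts
                    cy = rng.uniform(r, ts - r)
                    cx = rng.uniform(r, ts - r)
                    b = _blob((ts, ts), cy, cx, r, rng, tile_yy, tile_xx)
                    target[sl] |= b
                    for c, col in enumerate((0.45, 0.22, 0.55)):
                        img[sl][..., c][b] = col
            frac = 0.0 if blank[idx] else 1.0
            rows.append({"tile_col": w, "tile_row": psi, "tissue_fraction": frac, "blank": bool(blank[idx])})
    img += rng.normal(0.0, config.noise_sigma, img.shape)
    img = np.clip(img, 0, 1).astype(np.float32)
    return BlobMosaic(image=img, truth=pd.DataFrame(rows), target_mask=target)


def perturb_annotations(annotations: AnnotationSet, jitter: float, seed: int = 0) -> AnnotationSet:
    """Displace each mask boundary by smooth random noise of amplitude <= ``jitter`` px.

    The signed Euclidean distance to the boundary is perturbed by a
    low-pass-filtered noise field (standard deviation ``jitter / 2``,
    clipped at ``+/- jitter``) and re-thresholded, which moves the contour
    by at most ``jitter`` pixels while keeping it smooth.  ``jitter == 0``
    returns the input unchanged.
    """
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    if jitter == 0:
        return annotations
    rng = np.random.default_rng(seed)
    out = []
    for m in annotations.masks:
        signed = ndi.distance_transform_edt(m) - ndi.distance_transform_edt(~m)
        noise = ndi.gaussian_filter(rng.standard_normal(m.shape), 3.0)
        noise *= (jitter / 2) / max(noise.std(), 1e-9)
        np.clip(noise, -jitter, jitter, out=noise)
        out.append((signed + noise) > 0)
    return AnnotationSet.from_masks(out, annotations.image_shape)
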