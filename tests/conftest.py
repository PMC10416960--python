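"""Shared fixtures: toy-scale datasets and trained models.

Training at test time uses 64-px FISH-like tiles and a narrow DSL-FCN2s
(base 8 / head 32 channels, uniform skip-fusion scales) so a full training
run stays in the tens-of-seconds range on one CPU.  The trained models are
session-scoped and shared by every test that needs real predictions.
"""

import numpy as np
import pytest
from skimage.morphology import disk

from dslfcn.network import build_dsl_fcn2s
from dslfcn.softlabel import AnnotationSet, weight_map_for_annotations
from dslfcn.synthetic import FixtureConfig, PlacementError, make_fish_like_tile, perturb_annotations
from dslfcn.training import TrainConfig, TrainSample, train

TILE = 64
FISH_TILE_KW = dict(
    image_size=TILE,
    n_objects=3,
    nucleus_radius=(0.12, 0.18),
    dot_radius=(2.5, 4.0),
    dots_per_nucleus=(3, 6),
)
TOY_MODEL_KW = dict(base_channels=8, fc_channels=32, input_size=TILE, skip_scales=(1.0, 1.0, 1.0, 1.0))
TOY_TRAIN_KW = dict(learning_rate=1e-3, momentum=0.99, weight_decay=5e-4, normalization="pixels")


def collect_fish_tiles(n, seed_start):
    """Deterministically scan seeds, skipping rare unplaceable layouts."""
    tiles, seed = [], seed_start
    while len(tiles) < n:
        try:
            tiles.append(make_fish_like_tile(FixtureConfig(seed=seed, **FISH_TILE_KW)))
        except PlacementError:
            pass
        seed += 1
    return tiles


def soft_weight_for(tile, footprint=disk(1), jittered_nuclei=None):
    nuclei = jittered_nuclei if jittered_nuclei is not None else tile.nuclei
    masks = list(nuclei.masks) + list(tile.signals.masks)
    ann = AnnotationSet.from_masks(masks, tile.label.shape)
    return weight_map_for_annotations(ann, footprint).omega


def fish_samples(tiles, soft=True, jitter=0.0, jitter_seed=0):
    """TrainSamples from tiles; optional boundary jitter on the nucleus
    annotations feeds both the hard labels and the soft-weight map."""
    out = []
    for k, t in enumerate(tiles):
        nuclei = t.nuclei if jitter == 0 else perturb_annotations(t.nuclei, jitter, seed=jitter_seed + k)
        label = np.zeros_like(t.label)
        label[nuclei.union()] = 1
        label[t.signals.union()] = 2
        omega = soft_weight_for(t, jittered_nuclei=nuclei) if soft else None
        out.append(TrainSample(t.image, label, omega))
    return out


@pytest.fixture(scope="session")
def fish_fit_tiles():
    return collect_fish_tiles(12, 100)


@pytest.fixture(scope="session")
def fish_val_tiles():
    return collect_fish_tiles(4, 900)


@pytest.fixture(scope="session")
def trained_fish_model(fish_fit_tiles):
    """Toy DSL-FCN2s trained with the soft-weight loss on clean annotations."""
    model = build_dsl_fcn2s(3, **TOY_MODEL_KW, seed=0, dtype=np.float32)
    samples = fish_samples(fish_fit_tiles, soft=True)
    train(model, samples, TrainConfig(**TOY_TRAIN_KW, iterations=1200, seed=1))
    return model


def mosaic_samples(mosaic, tile_size=TILE):
    """Per-tile TrainSamples from a blob mosaic: 0 background, 1 tissue, 2 target."""
    out = []
    for _, row in mosaic.truth.iterrows():
        y0, x0 = row.tile_row * tile_size, row.tile_col * tile_size
        img = mosaic.image[y0 : y0 + tile_size, x0 : x0 + tile_size]
        label = np.zeros((tile_size, tile_size), np.int64)
        if not row.blank:
            label[:] = 1
            label[mosaic.target_mask[y0 : y0 + tile_size, x0 : x0 + tile_size]] = 2
        out.append(TrainSample(img.astype(np.float32), label))
    return out


@pytest.fixture(scope="session")
def trained_blob_model():
    """Toy DSL-FCN2s trained on bright-field mosaic tiles (tissue + targets)."""
    from dslfcn.synthetic import make_blob_mosaic

    mosaic = make_blob_mosaic(
        FixtureConfig(seed=2, image_size=256, n_objects=3, background="bright", blank_tile_fraction=6 / 16, tile_size=TILE)
    )
    model = build_dsl_fcn2s(3, **TOY_MODEL_KW, seed=0, dtype=np.float32)
    train(model, mosaic_samples(mosaic), TrainConfig(**TOY_TRAIN_KW, iterations=400, seed=1))
    return model
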