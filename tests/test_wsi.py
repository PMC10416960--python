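"""Tile addressing, foreground filtering, per-tile inference and stitching."""

import numpy as np
import pytest

from dslfcn.synthetic import FixtureConfig, make_blob_mosaic
from dslfcn.wsi import (
    SlideHandle,
    TileGrid,
    class_map,
    extract_target,
    foreground_filter,
    run_slide,
    stitch_tiles,
    tile_index,
)

MOSAIC_CFG = FixtureConfig(
    seed=2, image_size=256, n_objects=3, background="bright", blank_tile_fraction=6 / 16, tile_size=64
)


@pytest.fixture(scope="module")
def mosaic():
    return make_blob_mosaic(MOSAIC_CFG)


@pytest.fixture(scope="module")
def slide(mosaic):
    return SlideHandle(mosaic.image, alpha=64, beta=64)


class TestTileIndex:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (0, 0, (0, 0, 0, 0)),
            (1000, 600, (1, 1, 488, 88)),
            (511, 512, (0, 1, 511, 0)),
            (512, 511, (1, 0, 0, 511)),
        ],
    )
    def test_examples(self, a, b, expected):
        ti = tile_index(a, b, 512, 512)
        assert (ti.w, ti.psi, ti.i, ti.j) == expected

    def test_inverse_mapping_bijection(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            alpha, beta = rng.integers(1, 600, 2)
            a, b = int(rng.integers(0, 5000)), int(rng.integers(0, 5000))
            ti = tile_index(a, b, int(alpha), int(beta))
            assert ti.w * alpha + ti.i == a and ti.psi * beta + ti.j == b
            assert 0 <= ti.i < alpha and 0 <= ti.j < beta

    def test_negative_coordinates_rejected(self):
        with pytest.raises(ValueError):
            tile_index(-1, 0)

    def test_grid_counts_and_bounds(self):
        g = TileGrid(1000, 600, 512, 512)
        assert (g.n_cols, g.n_rows, len(g)) == (2, 2, 4)
        with pytest.raises(ValueError):
            g.index(1000, 0)


class TestForegroundFilter:
    def test_tissue_tile_kept_with_global_threshold(self, mosaic, slide):
        lvl = slide.thumbnail_level()
        thumb = slide.levels[lvl] @ np.array([0.2126, 0.7152, 0.0722])
        from skimage.filters import threshold_otsu

        otsu = float(threshold_otsu(thumb))
        tissue_row = mosaic.truth[~mosaic.truth.blank].iloc[0]
        tile = mosaic.image[
            tissue_row.tile_row * 64 : (tissue_row.tile_row + 1) * 64,
            tissue_row.tile_col * 64 : (tissue_row.tile_col + 1) * 64,
        ]
        kept, r = foreground_filter(tile, 0.70, "bright", otsu_threshold=otsu)
        assert kept and r > 0.9

    def test_uniform_background_tile_discarded(self):
        kept, r = foreground_filter(np.full((64, 64), 0.97), 0.70, "bright", otsu_threshold=0.9)
        assert not kept and r == 0.0

    def test_uniform_thumbnail_without_threshold_is_background(self):
        kept, r = foreground_filter(np.full((64, 64), 0.5), 0.70, "bright")
        assert not kept and r == 0.0

    def test_exactly_seventy_percent_is_discarded(self):
        """The boundary is exclusive: a tile at exactly the threshold goes."""
        tile = np.ones((10, 10))
        tile[:7] = 0.0  # dark = tissue on bright-field; exactly 70 of 100 px
        kept, r = foreground_filter(tile, 0.70, "bright", otsu_threshold=0.5)
        assert r == pytest.approx(0.70)
        assert not kept

    def test_dark_field_inverts_tissue_class(self):
        tile = np.zeros((8, 8))
        tile[:6] = 0.9  # bright = tissue on dark-field
        kept, r = foreground_filter(tile, 0.70, "dark", otsu_threshold=0.5)
        assert kept and r == pytest.approx(0.75)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        tile = rng.random((32, 32))
        kept_counts = []
        for thr in (0.2, 0.5, 0.8):
            kept, _ = foreground_filter(tile, thr, "bright", otsu_threshold=0.5)
            kept_counts.append(kept)
        assert kept_counts == sorted(kept_counts, reverse=True)


class TestClassMapAndTarget:
    def test_argmax_and_tie_break(self):
        probs = np.array([[[0.2]], [[0.3]], [[0.5]]])
        assert class_map(probs)[0, 0] == 2
        assert class_map(np.full((3, 1, 1), 1 / 3))[0, 0] == 0
        onehot = np.zeros((3, 2, 2))
        onehot[1] = 1
        assert (class_map(onehot) == 1).all()

    def test_extract_target_keeps_only_class_above_one(self):
        img = np.random.default_rng(0).random((4, 4, 3))
        s = np.indices((4, 4)).sum(axis=0) % 2 + 1  # checkerboard of 1/2
        t = extract_target(s, img)
        np.testing.assert_array_equal(t.mask, s == 2)
        np.testing.assert_array_equal(t.content[s == 2], img[s == 2])
        assert (t.content[s == 1] == 0).all()

    def test_all_target_and_no_target(self):
        img = np.ones((3, 3, 3))
        assert extract_target(np.full((3, 3), 2), img).mask.all()
        assert not extract_target(np.ones((3, 3), dtype=int), img).mask.any()

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            extract_target(np.zeros((2, 2)), np.zeros((3, 3, 3)))


class TestPredictTile:
    def test_probabilities_normalize_and_concentrate_on_dots(self, trained_fish_model, fish_val_tiles):
        from dslfcn.training import dice_score
        from dslfcn.wsi import predict_tile

        tile = fish_val_tiles[0]
        probs = predict_tile(trained_fish_model, tile.image)
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-9)
        assert dice_score(class_map(probs) == 2, tile.label == 2) >= 0.8

    def test_wrong_tile_geometry_rejected(self, trained_fish_model):
        from dslfcn.wsi import predict_tile

        with pytest.raises(ValueError):
            predict_tile(trained_fish_model, np.zeros((64, 64)))


class TestStitching:
    def test_roundtrip_is_bitwise_identity(self, mosaic, slide):
        tiles = {(w, psi): slide.tile(w, psi) for w, psi in slide.grid.tiles()}
        back = stitch_tiles(tiles, (256, 256), 64, 64)
        np.testing.assert_array_equal(back, slide.levels[0])

    def test_edge_tiles_padded_and_cropped(self):
        img = np.random.default_rng(3).random((100, 130, 3)).astype(np.float32)
        sh = SlideHandle(img, alpha=64, beta=64)
        t = sh.tile(1, 1, pad=True)
        assert t.shape == (64, 64, 3)
        assert (t[36:, :, :] == 0).all()  # zero padding below the slide edge
        tiles = {(w, psi): sh.tile(w, psi) for w, psi in sh.grid.tiles()}
        np.testing.assert_array_equal(stitch_tiles(tiles, (100, 130), 64, 64), img)


class _ConstantModel:
    """Stand-in model emitting fixed per-class scores."""

    def __init__(self, scores=(0.0, 0.0, 0.0)):
        self.scores = np.asarray(scores, dtype=float)

    def predict_scores(self, tile):
        h, w = tile.shape[:2]
        return np.tile(self.scores[:, None, None], (1, h, w))


class TestRunSlide:
    def test_blank_tiles_skipped_and_conserved(self, mosaic, slide):
        res = run_slide(_ConstantModel((1.0, 0.0, 0.0)), slide, 0.70, "bright")
        n_blank = int(mosaic.truth.blank.sum())
        assert res.metadata["n_discarded"] == n_blank == 6
        assert res.metadata["n_kept"] == 16 - n_blank
        assert res.metadata["n_kept"] + res.metadata["n_discarded"] == len(slide.grid)
        assert not res.report.failed.any()

    def test_uniform_probability_model_keeps_background_argmax(self, slide):
        res = run_slide(_ConstantModel((0.0, 0.0, 0.0)), slide, 0.70, "bright")
        assert not res.target_mask.any()

    def test_target_everywhere_model_marks_kept_tiles_only(self, mosaic, slide):
        res = run_slide(_ConstantModel((0.0, 0.0, 5.0)), slide, 0.70, "bright")
        for _, row in mosaic.truth.iterrows():
            y0, x0 = row.tile_row * 64, row.tile_col * 64
            block = res.target_mask[y0 : y0 + 64, x0 : x0 + 64]
            assert block.all() != row.blank
        report = res.report.set_index(["tile_col", "tile_row"])
        assert (report.loc[~report.kept, "target_pixels"] == 0).all()

    def test_stitch_locality_single_tile_perturbation(self, mosaic):
        """Changing one tile's pixels only changes that tile's output."""

        class ThresholdModel:
            def predict_scores(self, tile):
                bright = tile.mean(axis=2) > 0.5
                return np.stack([np.zeros_like(bright, float), (~bright).astype(float), bright.astype(float) * 2])

        base = run_slide(ThresholdModel(), SlideHandle(mosaic.image, 64, 64), 0.0, "bright")
        perturbed = mosaic.image.copy()
        perturbed[64:128, 64:128] = 1.0 - perturbed[64:128, 64:128]
        pert = run_slide(ThresholdModel(), SlideHandle(perturbed, 64, 64), 0.0, "bright")
        diff = base.class_map != pert.class_map
        assert not diff[:64].any() and not diff[128:].any()
        assert not diff[:, :64].any() and not diff[:, 128:].any()

    def test_stitched_segmentation_recovers_ground_truth(self, trained_blob_model):
        """End to end on an unseen mosaic: filter, segment, stitch; the
        stitched target mask overlaps the construction truth at Dice >= 0.8."""
        from dslfcn.training import dice_score

        test_mosaic = make_blob_mosaic(
            FixtureConfig(
                seed=33, image_size=256, n_objects=3, background="bright", blank_tile_fraction=4 / 16, tile_size=64
            )
        )
        res = run_slide(trained_blob_model, SlideHandle(test_mosaic.image, 64, 64), 0.70, "bright")
        assert res.metadata["n_discarded"] == int(test_mosaic.truth.blank.sum())
        assert dice_score(res.target_mask, test_mosaic.target_mask) >= 0.8

    def test_failing_tile_logged_and_skipped(self, slide):
        class BrokenModel:
            def predict_scores(self, tile):
                raise RuntimeError("boom")

        res = run_slide(BrokenModel(), slide, 0.70, "bright")
        assert res.report.failed.sum() == res.metadata["n_kept"]
        assert not res.target_mask.any()
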