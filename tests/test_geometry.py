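import numpy as np
import pytest

from cycleproc.experiment_model import GridSpec, TileKey, nominal_origin
from cycleproc.geometry import (
    MosaicLayout,
    Translation,
    apply_translation,
    compose_mosaic,
    crop_to_common,
    estimate_pairwise_offsets,
    estimate_translation,
    register_cycles,
    solve_global_positions,
)
from cycleproc.synthetic_acquisition import generate_phantom, render_tile
from cycleproc.testing import small_descriptor

from oracles import brute_force_shift


def textured(rng, shape=(64, 64)):
    return rng.uniform(0, 1000, size=shape)


class TestEstimateTranslation:
    def test_identical_images(self, rng):
        img = textured(rng)
        t = estimate_translation(img, img)
        assert (t.dx, t.dy) == (0.0, 0.0)
        assert t.quality == pytest.approx(1.0, abs=1e-6)

    def test_constructed_circular_shift(self, rng):
        ref = textured(rng)
        moving = np.roll(ref, (-2, 3), axis=(0, 1))  # content moves (dx=3, dy=-2)
        t = estimate_translation(ref, moving)
        assert (t.dx, t.dy) == (3.0, -2.0)
        # agrees with the exhaustive oracle
        assert brute_force_shift(ref, moving, 5) == (3, -2)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            estimate_translation(np.ones((16, 16)), np.ones((16, 16)))

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            estimate_translation(textured(rng), textured(rng, (32, 32)))

    def test_simulator_drift_recovery(self):
        desc = small_descriptor(n_cols=1, n_rows=1, n_cycles=2, n_channels=1)
        truth = generate_phantom(desc, n_nuclei=8, seed=30, max_drift=0,
                                 af_texture=200.0)
        truth.drift_vectors[2] = (5.0, 4.0)
        ref = render_tile(truth, TileKey(1, 1, 1, 1))
        mov = render_tile(truth, TileKey(2, 1, 1, 1))
        t = estimate_translation(ref, mov)
        assert abs(t.dx - 5.0) <= 0.5 and abs(t.dy - 4.0) <= 0.5

    def test_subpixel_quality_monotone(self, rng):
        ref = textured(rng)
        aligned = estimate_translation(ref, np.roll(ref, (1, 1), axis=(0, 1)))
        noisy = ref + rng.normal(0, 200, size=ref.shape)
        degraded = estimate_translation(ref, np.roll(noisy, (1, 1), axis=(0, 1)))
        assert aligned.quality > degraded.quality


class TestRegisterCycles:
    def test_single_cycle(self, rng):
        img = textured(rng)
        out = register_cycles({1: img}, reference_cycle=1)
        assert out[1].dx == 0.0 and out[1].dy == 0.0

    def test_reference_cycle_missing(self, rng):
        with pytest.raises(ValueError):
            register_cycles({2: textured(rng)}, reference_cycle=1)

    def test_known_integer_drifts_recovered_exactly(self, rng):
        ref = textured(rng, (96, 96))
        drifts = {1: (0, 0), 2: (3, -2), 3: (-1, 4)}
        tiles = {
            c: np.roll(ref, (dy, dx), axis=(0, 1)) for c, (dx, dy) in drifts.items()
        }
        out = register_cycles(tiles, reference_cycle=1)
        for c, (dx, dy) in drifts.items():
            assert (out[c].dx, out[c].dy) == (float(dx), float(dy))

    def test_same_translation_for_all_channels_by_contract(self, rng):
        # contract check: register_cycles yields one translation per cycle,
        # applied identically to every channel by crop_to_common
        ref = textured(rng, (48, 48))
        tiles_by_cycle = {1: ref, 2: np.roll(ref, (2, 1), axis=(0, 1))}
        translations = register_cycles(tiles_by_cycle, 1)
        imgs = {
            (c, ch): rng.uniform(0, 10, size=(48, 48))
            for c in (1, 2)
            for ch in (1, 2)
        }
        cropped = crop_to_common(imgs, translations)
        shapes = {v.shape for v in cropped.values()}
        assert len(shapes) == 1


class TestCropToCommon:
    def test_zero_translations_no_crop(self, rng):
        tiles = {(1, 1): textured(rng, (32, 40))}
        out = crop_to_common(tiles, {1: Translation(0.0, 0.0)})
        assert out[(1, 1)].shape == (32, 40)
        np.testing.assert_array_equal(out[(1, 1)], tiles[(1, 1)])

    def test_margin_arithmetic_2048(self):
        # max |dx| = 3, max |dy| = 2 -> 2044 rows x 2042 cols
        tile = np.zeros((2048, 2048), dtype=np.float32)
        translations = {1: Translation(0.0, 0.0), 2: Translation(3.0, -2.0)}
        out = crop_to_common({(1, 1): tile}, translations)
        assert out[(1, 1)].shape == (2048 - 4, 2048 - 6)

    def test_all_cycles_share_shape_and_framing(self, rng):
        base = textured(rng, (64, 64))
        drifts = {1: (0, 0), 2: (4, -3), 3: (-2, 5)}
        tiles = {
            (c, 1): np.roll(base, (dy, dx), axis=(0, 1))
            for c, (dx, dy) in drifts.items()
        }
        translations = {c: Translation(float(dx), float(dy)) for c, (dx, dy) in drifts.items()}
        out = crop_to_common(tiles, translations)
        shapes = {v.shape for v in out.values()}
        assert shapes == {(64 - 10, 64 - 8)}
        # per-pixel alignment is exact for integer drifts
        for c in (2, 3):
            np.testing.assert_array_equal(out[(c, 1)], out[(1, 1)])

    def test_crop_exceeding_tile_rejected(self, rng):
        tiles = {(1, 1): textured(rng, (16, 16))}
        with pytest.raises(ValueError):
            crop_to_common(tiles, {1: Translation(10.0, 0.0)})

    def test_missing_translation(self, rng):
        with pytest.raises(ValueError):
            crop_to_common({(5, 1): textured(rng)}, {1: Translation(0.0, 0.0)})


def make_grid_tiles(rng, grid, tile_w, tile_h, seam_error=None):
    """Cut overlapping tiles out of one textured global image.

    ``seam_error``: optional (position, (ex, ey)) stage error injected on one
    tile's true origin.
    """
    stride_x = int(round(tile_w * (1 - grid.overlap_fraction)))
    stride_y = int(round(tile_h * (1 - grid.overlap_fraction)))
    width = tile_w + (grid.n_cols - 1) * stride_x + 8
    height = tile_h + (grid.n_rows - 1) * stride_y + 8
    plane = rng.uniform(0, 1000, size=(height, width))
    tiles, origins = {}, {}
    for pos in range(1, grid.n_positions + 1):
        x0, y0 = nominal_origin(grid, tile_w, tile_h, pos)
        if seam_error and seam_error[0] == pos:
            x0 += seam_error[1][0]
            y0 += seam_error[1][1]
        tiles[pos] = plane[y0 : y0 + tile_h, x0 : x0 + tile_w]
        origins[pos] = (x0, y0)
    return tiles, origins


class TestPairwiseOffsets:
    def test_exact_nominal_overlap(self, rng):
        grid = GridSpec(n_cols=3, n_rows=2, overlap_fraction=0.1)
        tiles, _ = make_grid_tiles(rng, grid, 80, 80)
        offsets = estimate_pairwise_offsets(tiles, grid)
        assert len(offsets) == 2 * 2 + 3  # 4 horizontal + 3 vertical pairs on 3x2
        stride = 72
        for off in offsets:
            nominal = (stride, 0) if off.dy == 0 or abs(off.dx) > abs(off.dy) else (0, stride)
            assert abs(off.dx - nominal[0]) <= 1
            assert abs(off.dy - nominal[1]) <= 1
            assert not off.fallback

    def test_injected_seam_error_detected(self, rng):
        grid = GridSpec(n_cols=2, n_rows=1, overlap_fraction=0.2)
        tiles, origins = make_grid_tiles(rng, grid, 80, 80, seam_error=(2, (2, 0)))
        offsets = estimate_pairwise_offsets(tiles, grid)
        assert len(offsets) == 1
        off = offsets[0]
        true_dx = origins[2][0] - origins[1][0]
        assert off.dx == pytest.approx(true_dx, abs=0.5)
        assert off.dx - 64 == pytest.approx(2, abs=0.5)  # 2-px deviation from nominal

    def test_single_tile_grid_empty(self, rng):
        grid = GridSpec(n_cols=1, n_rows=1)
        assert estimate_pairwise_offsets({1: textured(rng)}, grid) == []

    def test_featureless_seam_falls_back(self):
        grid = GridSpec(n_cols=2, n_rows=1, overlap_fraction=0.2)
        tiles = {1: np.ones((40, 40)), 2: np.ones((40, 40))}
        offsets = estimate_pairwise_offsets(tiles, grid)
        assert offsets[0].fallback
        assert offsets[0].dx == 32.0  # nominal stride


class TestSolveGlobalPositions:
    def test_nominal_1x3_row(self, rng):
        # all offsets exactly nominal: W=200, overlap 10% -> x = 0, 180, 360
        grid = GridSpec(n_cols=3, n_rows=1, overlap_fraction=0.1)
        tiles, _ = make_grid_tiles(rng, grid, 200, 200)
        offsets = estimate_pairwise_offsets(tiles, grid)
        layout = solve_global_positions(offsets, grid, 200, 200)
        xs = sorted(x for x, _ in layout.positions.values())
        assert xs == [0, 180, 360]

    def test_single_tile(self):
        grid = GridSpec(n_cols=1, n_rows=1)
        layout = solve_global_positions([], grid, 100, 120)
        assert layout.positions == {1: (0, 0)}
        assert (layout.mosaic_width, layout.mosaic_height) == (100, 120)

    def test_2x2_ground_truth_recovery(self, rng):
        grid = GridSpec(n_cols=2, n_rows=2, overlap_fraction=0.15)
        tiles, origins = make_grid_tiles(rng, grid, 80, 80, seam_error=(3, (1, -2)))
        offsets = estimate_pairwise_offsets(tiles, grid)
        layout = solve_global_positions(offsets, grid, 80, 80)
        # compare relative positions to true origins (within 1 px)
        ox, oy = layout.positions[1]
        tx, ty = origins[1]
        for pos in origins:
            assert abs((layout.positions[pos][0] - ox) - (origins[pos][0] - tx)) <= 1
            assert abs((layout.positions[pos][1] - oy) - (origins[pos][1] - ty)) <= 1

    def test_disconnected_graph_rejected(self):
        grid = GridSpec(n_cols=2, n_rows=1)
        with pytest.raises(ValueError):
            solve_global_positions([], grid, 32, 32)


class TestComposeMosaic:
    def test_single_tile_identity(self, rng):
        tile = textured(rng, (32, 32))
        layout = MosaicLayout({1: (0, 0)}, 32, 32, 32, 32)
        np.testing.assert_allclose(compose_mosaic({1: tile}, layout), tile)

    def test_blend_of_identical_content_exact(self, rng):
        grid = GridSpec(n_cols=2, n_rows=1, overlap_fraction=0.25)
        tiles, origins = make_grid_tiles(rng, grid, 40, 40)
        offsets = estimate_pairwise_offsets(tiles, grid)
        layout = solve_global_positions(offsets, grid, 40, 40)
        mosaic = compose_mosaic(tiles, layout)
        # the overlap strips carry identical content; blending must reproduce it
        x2 = layout.positions[2][0]
        np.testing.assert_allclose(mosaic[:, x2:40], tiles[1][:, x2:40], atol=1e-9)

    def test_mosaic_matches_global_plane(self, rng):
        grid = GridSpec(n_cols=2, n_rows=2, overlap_fraction=0.2)
        stride = 64
        width = height = 80 + stride + 8
        plane = rng.uniform(0, 1000, size=(height, width))
        tiles = {}
        for pos in range(1, 5):
            x0, y0 = nominal_origin(grid, 80, 80, pos)
            tiles[pos] = plane[y0 : y0 + 80, x0 : x0 + 80]
        offsets = estimate_pairwise_offsets(tiles, grid)
        layout = solve_global_positions(offsets, grid, 80, 80)
        mosaic = compose_mosaic(tiles, layout)
        np.testing.assert_allclose(mosaic, plane[: layout.mosaic_height, : layout.mosaic_width], atol=1e-9)

    def test_wrong_tile_shape_rejected(self, rng):
        layout = MosaicLayout({1: (0, 0)}, 32, 32, 32, 32)
        with pytest.raises(ValueError):
            compose_mosaic({1: textured(rng, (16, 16))}, layout)

    def test_layout_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            MosaicLayout({1: (10, 0)}, 32, 32, 32, 32)


class TestApplyTranslation:
    def test_integer_roll_inverse(self, rng):
        ref = textured(rng)
        moved = np.roll(ref, (4, -3), axis=(0, 1))  # dx=-3, dy=4
        back = apply_translation(moved, Translation(dx=-3.0, dy=4.0))
        np.testing.assert_array_equal(back, ref)

    def test_subpixel_path_runs(self, rng):
        ref = textured(rng)
        out = apply_translation(ref, Translation(dx=0.5, dy=-0.25))
        assert out.shape == ref.shape
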