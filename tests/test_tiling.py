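import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stainpipe import (
    Tile,
    TileSpec,
    extract_tiles,
    maybe_reflect,
    plan_tiles,
    pre_rotation_side,
    rescale_to_magnification,
    rotate_and_crop,
    segment_tissue,
)
from stainpipe.errors import ConfigurationError, InvalidInputError


def brute_force_block_mean(img, factor):
    h = img.shape[0] // factor
    w = img.shape[1] // factor
    out = np.zeros((h, w, img.shape[2]))
    for i in range(h):
        for j in range(w):
            block = img[i * factor : (i + 1) * factor, j * factor : (j + 1) * factor]
            out[i, j] = block.reshape(-1, img.shape[2]).mean(axis=0)
    return out


def brute_force_otsu_partition(values, nbins=256):
    """Exhaustive between-class-variance scan over every cut of a
    256-bin intensity histogram; returns the boolean 'dark class'
    partition (values strictly below the maximizing bin centre)."""
    v = values.ravel().astype(np.float64)
    counts, edges = np.histogram(v, bins=nbins, range=(v.min(), v.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_var, best_thr = -1.0, None
    for k in range(nbins - 1):
        n0 = counts[: k + 1].sum()
        n1 = counts[k + 1 :].sum()
        if n0 == 0 or n1 == 0:
            continue
        mu0 = (counts[: k + 1] * centers[: k + 1]).sum() / n0
        mu1 = (counts[k + 1 :] * centers[k + 1 :]).sum() / n1
        var = (n0 / v.size) * (n1 / v.size) * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_thr = var, centers[k]
    return (values < best_thr).reshape(values.shape)


class TestGeometryConstant:
    def test_pre_rotation_side_is_316(self):
        assert pre_rotation_side(224) == 316


class TestRescale:
    def test_identity_at_matching_magnification(self):
        img = np.random.default_rng(0).integers(0, 256, (64, 64, 3), dtype=np.uint8)
        out = rescale_to_magnification(img, 10)
        assert out is img  # bit-identical, no copy

    def test_x40_block_mean_oracle(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 255, (400, 400, 3))
        out = rescale_to_magnification(img, 40)
        assert out.shape == (100, 100, 3)
        np.testing.assert_allclose(out, brute_force_block_mean(img, 4), atol=1e-9)

    def test_x20_block_mean_oracle(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 255, (50, 70, 3))
        out = rescale_to_magnification(img, 20)
        np.testing.assert_allclose(out, brute_force_block_mean(img, 2), atol=1e-9)

    def test_unsupported_magnification(self):
        img = np.zeros((8, 8, 3))
        with pytest.raises(ConfigurationError):
            rescale_to_magnification(img, 60)
        with pytest.raises(ConfigurationError):
            rescale_to_magnification(img, 40, TileSpec(target_magnification=40 + 1))


class TestSegmentTissue:
    def test_uniform_white_gives_empty_mask(self):
        img = np.full((32, 32, 3), 255, dtype=np.uint8)
        assert not segment_tissue(img).any()

    def test_half_dark_half_bright(self):
        img = np.empty((20, 40, 3), dtype=np.uint8)
        img[:, :20] = 50
        img[:, 20:] = 250
        mask = segment_tissue(img)
        expected = np.zeros((20, 40), dtype=bool)
        expected[:, :20] = True
        assert np.array_equal(mask, expected)
        assert np.array_equal(mask, brute_force_otsu_partition(img[..., 0]))

    def test_matches_exhaustive_scan_on_bimodal_images(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            dark = rng.normal(70, 12, (40, 40))
            bright = rng.normal(220, 10, (40, 40))
            pick = rng.random((40, 40)) < 0.4
            gray = np.clip(np.where(pick, dark, bright), 0, 255).astype(np.uint8)
            img = np.stack([gray] * 3, axis=-1)
            mask = segment_tissue(img)
            assert np.array_equal(mask, brute_force_otsu_partition(gray))

    def test_generator_truth_iou(self, small_slide):
        mask = segment_tissue(small_slide.image)
        truth = small_slide.truth_mask
        iou = (mask & truth).sum() / (mask | truth).sum()
        assert iou >= 0.90


class TestPlanTiles:
    def test_448_grid_is_3x3(self):
        assert len(plan_tiles(448, 448, 224, 112)) == 9

    def test_too_small_image_empty(self):
        assert plan_tiles(200, 200, 224, 112) == []

    def test_matches_exhaustive_enumeration(self):
        positions = plan_tiles(500, 300, 224, 56)
        brute = [
            (r, c)
            for r in range(0, 500, 56)
            for c in range(0, 300, 56)
            if r + 224 <= 500 and c + 224 <= 300
        ]
        assert positions == brute

    def test_row_major_and_in_bounds(self):
        pos = plan_tiles(700, 500, 224, 112)
        assert pos == sorted(pos)
        assert all(r + 224 <= 700 and c + 224 <= 500 for r, c in pos)

    @given(
        h=st.integers(224, 900),
        w=st.integers(224, 900),
        stride=st.integers(28, 224),
    )
    @settings(max_examples=30, deadline=None)
    def test_halving_stride_supersets_positions(self, h, w, stride):
        if stride % 2:
            stride += 1
        coarse = set(plan_tiles(h, w, 224, stride))
        fine = set(plan_tiles(h, w, 224, stride // 2))
        assert coarse <= fine
        assert len(fine) >= len(coarse)


class TestExtractTiles:
    def _img_mask(self, seed=0, h=600, w=600):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (h, w, 3), dtype=np.uint8)
        mask = rng.random((h, w)) < 0.15
        return img, mask

    def test_all_false_mask_gives_no_tiles(self):
        img, _ = self._img_mask()
        assert extract_tiles(img, np.zeros((600, 600), bool)) == []

    def test_retention_matches_brute_force(self):
        img, mask = self._img_mask(seed=4)
        spec = TileSpec()
        tiles = extract_tiles(img, mask, spec, mode="inference")
        got = {(t.row, t.col) for t in tiles}
        expected = set()
        for r, c in plan_tiles(600, 600, 224, 112):
            if mask[r : r + 224, c : c + 224].mean() >= 0.10:
                expected.add((r, c))
        assert got == expected
        for t in tiles:
            assert t.tissue_fraction == mask[
                t.row : t.row + 224, t.col : t.col + 224
            ].mean()

    def test_exactly_ten_percent_is_retained(self):
        # 220x220 window: 10% of 48400 pixels is a whole number, so the
        # tissue fraction hits the threshold exactly; >= keeps the tile
        img = np.zeros((220, 220, 3), dtype=np.uint8)
        mask = np.zeros((220, 220), bool)
        mask.ravel()[: 220 * 220 // 10] = True
        assert mask.mean() == 0.10
        spec = TileSpec(tile_size=220, stride=220)
        tiles = extract_tiles(img, mask, spec)
        assert len(tiles) == 1 and tiles[0].tissue_fraction == 0.10
        mask.ravel()[0] = False  # one pixel below threshold -> dropped
        assert extract_tiles(img, mask, spec) == []

    def test_training_mode_uses_316_and_56(self):
        img, _ = self._img_mask(seed=5, h=700, w=700)
        mask = np.ones((700, 700), bool)
        tiles = extract_tiles(img, mask, TileSpec(), mode="training")
        assert all(t.size == 316 for t in tiles)
        rows = sorted({t.row for t in tiles})
        assert rows == list(range(0, 700 - 316 + 1, 56))

    def test_shape_mismatch_rejected(self):
        img, _ = self._img_mask()
        with pytest.raises(InvalidInputError):
            extract_tiles(img, np.zeros((10, 10), bool))

    def test_windows_fully_inside_image(self):
        img, mask = self._img_mask(seed=6, h=500, w=460)
        for t in extract_tiles(img, mask, TileSpec(min_tissue_fraction=0.0)):
            assert t.row + t.size <= 500 and t.col + t.size <= 460


def _square_tile(side=316, seed=0):
    rng = np.random.default_rng(seed)
    return Tile(
        pixels=rng.integers(0, 256, (side, side, 3), dtype=np.uint8),
        row=0,
        col=0,
        tissue_fraction=1.0,
    )


class TestRotateAndCrop:
    def test_angle_zero_is_exact_centre_crop(self):
        tile = _square_tile()
        out = rotate_and_crop(tile, 0.0)
        off = (316 - 224) // 2
        assert np.array_equal(out.pixels, tile.pixels[off : off + 224, off : off + 224])

    def test_angle_90_matches_rot90_oracle(self):
        tile = _square_tile(seed=1)
        out = rotate_and_crop(tile, 90.0)
        off = (316 - 224) // 2
        oracle = np.rot90(tile.pixels)[off : off + 224, off : off + 224]
        assert np.array_equal(out.pixels, oracle)

    def test_angle_45_fringe_is_subpixel(self):
        # black tile, white fill: any fill bleed shows up as bright pixels
        tile = Tile(np.zeros((316, 316, 3), np.uint8), 0, 0, 1.0)
        out = rotate_and_crop(tile, 45.0)
        n_touched = int((out.pixels > 0).any(axis=2).sum())
        assert n_touched <= 40  # only a sub-pixel fringe at 4 corners

    @pytest.mark.parametrize("angle", [0.0, 17.3, 45.0, 90.0, 133.7, 270.0, 359.9])
    def test_dtype_range_and_side_preserved(self, angle):
        tile = _square_tile(seed=2)
        out = rotate_and_crop(tile, angle)
        assert out.pixels.shape == (224, 224, 3)
        assert out.pixels.dtype == np.uint8

    def test_undersized_tile_rejected(self):
        tile = _square_tile(side=100)
        with pytest.raises(InvalidInputError):
            rotate_and_crop(tile, 10.0)


class TestMaybeReflect:
    def test_p_zero_is_identity(self):
        tile = _square_tile(side=32)
        out = maybe_reflect(tile, 0.0, np.random.default_rng(0))
        assert np.array_equal(out.pixels, tile.pixels)

    def test_p_one_twice_is_identity(self):
        tile = _square_tile(side=32, seed=3)
        rng = np.random.default_rng(0)
        out = maybe_reflect(maybe_reflect(tile, 1.0, rng), 1.0, rng)
        assert np.array_equal(out.pixels, tile.pixels)

    def test_reflection_reverses_columns(self):
        tile = _square_tile(side=16, seed=4)
        out = maybe_reflect(tile, 1.0, np.random.default_rng(0))
        assert np.array_equal(out.pixels, tile.pixels[:, ::-1])

    def test_binomial_fraction_near_half(self):
        tile = _square_tile(side=4, seed=5)
        rng = np.random.default_rng(123)
        n = 10_000
        flips = sum(
            not np.array_equal(maybe_reflect(tile, 0.5, rng).pixels, tile.pixels)
            for _ in range(n)
        )
        se = 0.5 / np.sqrt(n)
        assert abs(flips / n - 0.5) < 3 * se

    def test_invalid_probability(self):
        with pytest.raises(InvalidInputError):
            maybe_reflect(_square_tile(side=4), 1.5)
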