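"""Grid planning, cropping, splitting, and mask I/O round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bollseg.tiling import (
    crop_tiles,
    plan_grid,
    rasterize_polygons,
    read_mask,
    split_dataset,
    write_mask,
)


def brute_force_min_cover(extent: int, tile_size: int) -> int:
    """Smallest n such that n tiles of width tile_size can cover extent px."""
    n = 1
    while n * tile_size < extent:
        n += 1
    return n


class TestPlanGrid:
    def test_exact_divisible(self):
        grid = plan_grid(600, 600, 300, "exact")
        assert (grid.n_cols, grid.n_rows) == (2, 2)
        assert set(grid.origins) == {(x, y) for x in (0, 300) for y in (0, 300)}

    def test_exact_non_divisible_fails(self):
        with pytest.raises(ValueError, match="divide"):
            plan_grid(650, 600, 300, "exact")

    def test_fixed_grid_matches_uav_frame_convention(self):
        # 20 x 10 lattice of 300-px tiles over a 5472 x 3078 frame -> 200 tiles
        grid = plan_grid(5472, 3078, 300, "fixed-grid", n_cols=20, n_rows=10)
        assert len(grid.origins) == 200
        for x, y in grid.origins:
            assert 0 <= x <= 5472 - 300 and 0 <= y <= 3078 - 300

    @pytest.mark.parametrize(
        "w,h,ts", [(650, 420, 300), (5472, 3078, 300), (100, 100, 33), (64, 96, 32)]
    )
    def test_full_cover_count_matches_brute_force(self, w, h, ts):
        grid = plan_grid(w, h, ts, "full-cover")
        assert grid.n_cols == brute_force_min_cover(w, ts)
        assert grid.n_rows == brute_force_min_cover(h, ts)

    def test_full_cover_covers_every_pixel(self):
        w, h, ts = 650, 430, 300
        grid = plan_grid(w, h, ts, "full-cover")
        covered = np.zeros((h, w), dtype=bool)
        for x, y in grid.origins:
            covered[y : y + ts, x : x + ts] = True
        assert covered.all()

    def test_oversized_tile_rejected(self):
        with pytest.raises(ValueError):
            plan_grid(100, 100, 128, "full-cover")


class TestCropTiles:
    def test_constant_image_gives_constant_tiles(self):
        img = np.full((64, 64, 3), 7, dtype=np.uint8)
        mask = np.zeros((64, 64), dtype=np.uint8)
        grid = plan_grid(64, 64, 32, "exact")
        tiles = crop_tiles(img, mask, grid)
        assert len(tiles) == 4
        assert all((t.image == 7).all() for t in tiles)

    def test_exact_tiles_reassemble_original(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(96, 64, 3), dtype=np.uint8)
        mask = rng.integers(0, 2, size=(96, 64), dtype=np.uint8)
        grid = plan_grid(64, 96, 32, "exact")
        tiles = crop_tiles(img, mask, grid)
        rebuilt = np.zeros_like(img)
        for (x, y), t in zip(grid.origins, tiles):
            rebuilt[y : y + 32, x : x + 32] = t.image
        assert np.array_equal(rebuilt, img)

    def test_full_cover_every_pixel_in_some_tile(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, size=(70, 90, 3), dtype=np.uint8)
        marker = np.arange(70 * 90, dtype=np.uint8).reshape(70, 90) % 2
        grid = plan_grid(90, 70, 32, "full-cover")
        tiles = crop_tiles(img, marker, grid)
        seen = np.zeros((70, 90), dtype=bool)
        for (x, y), t in zip(grid.origins, tiles):
            assert np.array_equal(t.mask, marker[y : y + 32, x : x + 32])
            seen[y : y + 32, x : x + 32] = True
        assert seen.all()

    def test_size_mismatch_rejected(self):
        grid = plan_grid(64, 64, 32, "exact")
        with pytest.raises(ValueError, match="differ"):
            crop_tiles(np.zeros((64, 64, 3)), np.zeros((32, 64)), grid)


class TestSplitDataset:
    def test_published_split_sizes(self):
        split = split_dataset(list(range(4000)), 0.8, seed=0)
        assert (len(split.train), len(split.test)) == (3200, 800)

    def test_deterministic_membership(self):
        a = split_dataset(list(range(10)), 0.8, seed=3)
        b = split_dataset(list(range(10)), 0.8, seed=3)
        assert a.train == b.train and a.test == b.test

    def test_partition_no_overlap(self):
        split = split_dataset(list(range(10)), 0.8, seed=1)
        assert set(split.train).isdisjoint(split.test)
        assert sorted(split.train + split.test) == list(range(10))

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([], 0.8, seed=0)

    @given(n=st.integers(2, 500), frac=st.floats(0.05, 0.95), seed=st.integers(0, 99))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_split_is_partition_with_rounded_sizes(self, n, frac, seed):
        split = split_dataset(list(range(n)), frac, seed)
        assert len(split.train) == int(np.floor(frac * n + 0.5))
        assert sorted(split.train + split.test) == list(range(n))


class TestMaskIO:
    @pytest.mark.parametrize("fill", ["zeros", "random"])
    def test_roundtrip_lossless(self, tmp_path, fill):
        rng = np.random.default_rng(0)
        mask = (
            np.zeros((40, 50), dtype=np.uint8)
            if fill == "zeros"
            else rng.integers(0, 2, size=(40, 50), dtype=np.uint8)
        )
        p = tmp_path / "m.png"
        write_mask(mask, p)
        assert np.array_equal(read_mask(p), mask)

    def test_three_valued_png_rejected(self, tmp_path):
        from PIL import Image

        arr = np.array([[0, 128], [255, 0]], dtype=np.uint8)
        p = tmp_path / "bad.png"
        Image.fromarray(arr, mode="L").save(p)
        with pytest.raises(ValueError, match="128"):
            read_mask(p)

    def test_nonbinary_in_memory_mask_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="2"):
            write_mask(np.array([[0, 2]]), tmp_path / "x.png")


class TestPolygons:
    def test_square_ring_rasterizes_interior(self):
        polys = [{"label": "cotton", "points": [[2, 2], [8, 2], [8, 8], [2, 8]]}]
        mask = rasterize_polygons(polys, (12, 12))
        assert mask[5, 5] == 1
        assert mask[0, 0] == 0
        assert mask.sum() == 36  # crossing-number convention: centers with x, y in [2, 8)

    def test_even_odd_hole(self):
        polys = [
            {"label": "cotton", "points": [[1, 1], [11, 1], [11, 11], [1, 11]]},
            {"label": "cotton", "points": [[4, 4], [8, 4], [8, 8], [4, 8]]},
        ]
        mask = rasterize_polygons(polys, (13, 13))
        assert mask[2, 2] == 1  # inside outer ring only
        assert mask[6, 6] == 0  # inside both rings -> hole

    def test_other_labels_ignored(self):
        polys = [{"label": "weed", "points": [[0, 0], [9, 0], [9, 9], [0, 9]]}]
        assert rasterize_polygons(polys, (10, 10)).sum() == 0
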