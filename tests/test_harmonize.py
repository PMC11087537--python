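"""Harmonisation operations against hand values and brute-force oracles."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon, box

from conftest import make_map
from cropmapeval import (
    BinaryCropMap,
    ClassRaster,
    CropClassRule,
    GridSpec,
    binarize,
    clip_to_boundary,
    mapped_area,
    mode_composite,
    resample_to_grid,
)


def codes_raster(values, grid=None):
    values = np.asarray(values, dtype=np.int64)
    h, w = values.shape
    grid = grid or GridSpec(0.0, float(h), 1.0, w, h)
    return ClassRaster(grid, values, np.zeros((h, w), dtype=bool), kind="codes")


def cont_raster(values, grid=None):
    values = np.asarray(values, dtype=float)
    h, w = values.shape
    grid = grid or GridSpec(0.0, float(h), 1.0, w, h)
    return ClassRaster(grid, values, np.zeros((h, w), dtype=bool), kind="continuous")


class TestBinarize:
    def test_strict_threshold(self):
        # probability layers: crop iff value strictly above 0.5
        r = cont_raster([[0.6, 0.5], [0.51, 0.49]])
        out = binarize(r, CropClassRule.threshold(0.5, strict=True))
        np.testing.assert_array_equal(out.values, [[1, 0], [1, 0]])

    def test_fraction_range_inclusive(self):
        # crop-area-fraction masks: 5-95% inclusive on both ends
        r = cont_raster([[50.0, 4.0], [96.0, 5.0], [95.0, 0.0]])
        out = binarize(r, CropClassRule.fraction_range(5, 95))
        np.testing.assert_array_equal(out.values, [[1, 0], [0, 1], [1, 0]])

    def test_code_set_membership(self):
        r = codes_raster([[11, 30, 14]])
        out = binarize(r, CropClassRule.code_set({11, 14, 20}))
        np.testing.assert_array_equal(out.values, [[1, 0, 1]])

    def test_mode_then_code_composites_first(self):
        stack = [codes_raster(v) for v in ([[4, 7]], [[4, 2]], [[5, 2]])]
        out = binarize(stack, CropClassRule.mode_then_code(4))
        np.testing.assert_array_equal(out.values, [[1, 0]])

    def test_domain_mismatch_rejected(self):
        with pytest.raises(ValueError):
            binarize(codes_raster([[1, 2]]), CropClassRule.fraction_range(5, 95))
        with pytest.raises(ValueError):
            binarize(cont_raster([[0.3, 0.7]]), CropClassRule.code_set({1}))

    def test_nodata_preserved(self):
        r = cont_raster([[0.9, 0.1]])
        r.nodata[0, 1] = True
        out = binarize(r, CropClassRule.threshold(0.5))
        assert out.nodata[0, 1] and not out.nodata[0, 0]


class TestModeComposite:
    def test_identical_stack_is_identity(self):
        r = codes_raster([[3, 5], [7, 9]])
        out = mode_composite([r, r, r])
        np.testing.assert_array_equal(out.values, r.values)

    def test_majority_and_tie(self):
        stack = [codes_raster([[4, 4]]), codes_raster([[4, 7]]), codes_raster([[7, 7]])]
        out = mode_composite(stack)
        assert out.values[0, 0] == 4  # majority
        assert out.values[0, 1] == 7
        tie = mode_composite([codes_raster([[4]]), codes_raster([[7]])])
        assert tie.values[0, 0] == 4  # tie -> lowest code

    def test_against_brute_force_frequency_count(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            T, h, w = rng.integers(1, 6), 5, 4
            stack = [codes_raster(rng.integers(0, 5, (h, w))) for _ in range(T)]
            out = mode_composite(stack)
            for r in range(h):
                for c in range(w):
                    series = [s.values[r, c] for s in stack]
                    best = min(set(series), key=lambda v: (-series.count(v), v))
                    assert out.values[r, c] == best

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            mode_composite([])


class TestResample:
    def test_exact_nesting_expands_blocks(self):
        coarse = make_map([[1, 0], [0, 1]], grid=GridSpec(0, 4, 2.0, 2, 2))
        target = GridSpec(0, 4, 1.0, 4, 4)
        out = resample_to_grid(coarse, target)
        expect = np.repeat(np.repeat([[1, 0], [0, 1]], 2, 0), 2, 1)
        np.testing.assert_array_equal(out.values, expect)

    def test_identity_on_same_grid(self):
        m = make_map([[1, 0], [1, 1]])
        out = resample_to_grid(m, m.grid)
        np.testing.assert_array_equal(out.values, m.values)

    def test_misaligned_against_brute_force_lookup(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            sh, sw = rng.integers(2, 8, 2)
            src = make_map(rng.integers(0, 2, (sh, sw)),
                           grid=GridSpec(rng.uniform(-2, 2), rng.uniform(5, 12),
                                         float(rng.integers(1, 4)), int(sw), int(sh)))
            tg, th, tw = rng.uniform(0.4, 2.5), rng.integers(2, 8), rng.integers(2, 8)
            target = GridSpec(src.grid.origin_x + rng.uniform(-1, 1),
                              src.grid.origin_y + rng.uniform(-1, 1),
                              float(tg), int(tw), int(th))
            out = resample_to_grid(src, target)
            for r in range(int(th)):
                for c in range(int(tw)):
                    x = target.origin_x + (c + 0.5) * target.pixel_size
                    y = target.origin_y - (r + 0.5) * target.pixel_size
                    sr, sc = src.grid.cell_index(x, y)
                    if 0 <= sr < sh and 0 <= sc < sw:
                        assert out.values[r, c] == src.values[sr, sc]
                        assert not out.nodata[r, c]
                    else:
                        assert out.nodata[r, c]

    def test_disjoint_extents_rejected(self):
        m = make_map([[1]])
        with pytest.raises(ValueError):
            resample_to_grid(m, GridSpec(100.0, 100.0, 1.0, 2, 2))


class TestClip:
    def test_full_cover_is_identity(self):
        m = make_map(np.eye(4, dtype=int))
        out = clip_to_boundary(m, box(-1, -1, 5, 5))
        np.testing.assert_array_equal(out.values, m.values)
        assert not out.nodata.any()

    def test_left_half_keeps_left_pixels(self):
        m = make_map(np.ones((4, 4), dtype=int))
        out = clip_to_boundary(m, box(0, 0, 2, 4))
        assert out.nodata[:, 2:].all() and not out.nodata[:, :2].any()

    def test_random_polygon_against_point_in_polygon(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            h, w = rng.integers(3, 9, 2)
            m = make_map(rng.integers(0, 2, (h, w)))
            pts = rng.uniform(-1, max(h, w) + 1, (5, 2))
            poly = Polygon(pts).convex_hull
            if poly.area == 0:
                continue
            out = clip_to_boundary(m, poly)
            for r in range(int(h)):
                for c in range(int(w)):
                    center = Point(c + 0.5, h - r - 0.5)
                    inside = poly.covers(center)
                    assert out.nodata[r, c] == (not inside)
                    if inside:
                        assert out.values[r, c] == m.values[r, c]

    def test_disjoint_boundary_warns_all_nodata(self):
        m = make_map([[1, 0]])
        with pytest.warns(UserWarning):
            out = clip_to_boundary(m, box(50, 50, 60, 60))
        assert out.nodata.all()


class TestMappedArea:
    def test_all_crop(self):
        area = mapped_area(make_map(np.ones((10, 10), dtype=int)))
        assert (area.n_pos, area.n_neg) == (100, 0)

    def test_all_non_crop_gives_degenerate_weights(self):
        from cropmapeval import AreaWeights

        area = mapped_area(make_map(np.zeros((30, 30), dtype=int)))
        w = AreaWeights.from_mapped_area(area)
        assert (w.w_neg, w.w_pos) == (1.0, 0.0)

    def test_counts_equal_brute_force(self):
        rng = np.random.default_rng(2)
        vals = rng.integers(0, 2, (12, 9))
        nodata = rng.random((12, 9)) < 0.2
        m = make_map(vals, nodata=nodata)
        area = mapped_area(m)
        pos = sum(int(vals[r, c]) for r in range(12) for c in range(9) if not nodata[r, c])
        tot = sum(1 for r in range(12) for c in range(9) if not nodata[r, c])
        assert area.n_pos == pos and area.n == tot

    def test_all_nodata_rejected(self):
        m = make_map([[1, 0]], nodata=[[True, True]])
        with pytest.raises(ValueError):
            mapped_area(m)


class TestInvariants:
    def test_binarize_resample_commute_on_nested_grids(self):
        rng = np.random.default_rng(4)
        vals = rng.random((4, 4))
        coarse = GridSpec(0, 8, 2.0, 4, 4)
        fine = GridSpec(0, 8, 1.0, 8, 8)
        rule = CropClassRule.threshold(0.5)
        raster = ClassRaster(coarse, vals, np.zeros((4, 4), bool), kind="continuous")

        a = resample_to_grid(binarize(raster, rule), fine)
        up = np.repeat(np.repeat(vals, 2, 0), 2, 1)
        b = binarize(ClassRaster(fine, up, np.zeros((8, 8), bool), kind="continuous"), rule)
        np.testing.assert_array_equal(a.values, b.values)

    def test_clip_preserves_retained_values(self):
        rng = np.random.default_rng(5)
        m = make_map(rng.integers(0, 2, (6, 6)))
        out = clip_to_boundary(m, box(1, 1, 5, 5))
        keep = ~out.nodata
        np.testing.assert_array_equal(out.values[keep], m.values[keep])

    def test_mapped_area_partition(self):
        rng = np.random.default_rng(6)
        m = make_map(rng.integers(0, 2, (7, 7)), nodata=rng.random((7, 7)) < 0.3)
        area = mapped_area(m)
        assert area.n_neg + area.n_pos == int(m.valid.sum())
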