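"""Geometry tests: connected components, CEJ localization, root length,
BL%, the 2 mm retention filter, and region-apex association."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from periostage.image_io import Point2D
from periostage.measurement import (
    CalibrationConfig,
    RegionMeasurement,
    associate_regions_to_apexes,
    euclidean_distance,
    find_bl_regions,
    locate_cej_center,
    measure_tooth,
)


def _rect_mask(shape, rows, cols):
    m = np.zeros(shape, dtype=np.uint8)
    m[rows[0] : rows[1] + 1, cols[0] : cols[1] + 1] = 1
    return m


class TestFindBlRegions:
    def test_single_rectangle(self):
        mask = _rect_mask((100, 100), (10, 39), (20, 29))  # 10 wide, 30 tall
        regions = find_bl_regions(mask)
        assert len(regions) == 1
        assert regions[0].max_height == 30
        assert regions[0].bbox == (20, 10, 10, 30)
        assert regions[0].area == 300

    def test_two_disjoint_squares(self):
        mask = np.zeros((60, 60), dtype=np.uint8)
        mask[5:10, 5:10] = 1  # 5x5
        mask[30:37, 40:43] = 1  # 3 wide, 7 tall
        heights = sorted(r.max_height for r in find_bl_regions(mask, min_area=1))
        assert heights == [5, 7]

    def test_l_shape_height_matches_pixel_extent(self):
        mask = np.zeros((40, 40), dtype=np.uint8)
        mask[4:20, 5:9] = 1
        mask[16:20, 5:25] = 1
        regions = find_bl_regions(mask)
        assert len(regions) == 1
        rows = np.nonzero(mask)[0]
        assert regions[0].max_height == rows.max() - rows.min() + 1 == 16

    def test_min_area_suppresses_speckle(self):
        mask = np.zeros((50, 50), dtype=np.uint8)
        mask[0:2, 0:2] = 1  # 4 px speckle
        mask[10:40, 10:20] = 1
        assert len(find_bl_regions(mask, min_area=20)) == 1

    def test_empty_mask(self):
        assert find_bl_regions(np.zeros((10, 10), dtype=np.uint8)) == []


class TestLocateCej:
    def test_rectangle_lower_and_upper(self):
        mask = _rect_mask((100, 100), (40, 69), (10, 19))
        region = find_bl_regions(mask)[0]
        assert locate_cej_center(region, "lower").as_tuple() == (14, 40)
        assert locate_cej_center(region, "upper").as_tuple() == (14, 69)

    def test_invalid_jaw(self):
        region = RegionMeasurement(1, (0, 0, 5, 5), 5, 25)
        with pytest.raises(ValueError):
            locate_cej_center(region, "left")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_irregular_blob_matches_pixel_bbox(self, seed):
        """CEJ x = floored bbox midpoint, y = extreme row of member pixels."""
        rng = np.random.default_rng(seed)
        mask = np.zeros((30, 30), dtype=np.uint8)
        n = rng.integers(21, 60)
        ys = rng.integers(2, 28, n)
        xs = rng.integers(2, 28, n)
        # grow a connected blob around a seed pixel for realism of shape
        mask[ys[0] : ys[0] + 3, xs[0] : xs[0] + 3] = 1
        mask[ys % 28, xs % 28] = 1
        regions = find_bl_regions(mask, min_area=1)
        for region in regions:
            pix_r, pix_c = np.nonzero(
                _region_pixels(mask, region)
            )
            cej = locate_cej_center(region, "lower")
            assert cej.y == pix_r.min()
            assert cej.x == (pix_c.min() + pix_c.max()) // 2


def _region_pixels(mask, region):
    from skimage.measure import label

    lab = label(mask, connectivity=2)
    return lab == region.region_id


@pytest.mark.parametrize(
    "p1, p2, expected",
    [((0, 0), (3, 4), 5.0), ((2, 7), (2, 7), 0.0), ((2, 7), (-1, 3), 5.0)],
)
def test_euclidean_distance(p1, p2, expected):
    assert euclidean_distance(Point2D(*p1), Point2D(*p2)) == pytest.approx(expected)


class TestMeasureTooth:
    def _region(self, height, cej=(50, 40)):
        # rectangle centered on cej x with odd width 21
        x0 = cej[0] - 10
        return RegionMeasurement(1, (x0, cej[1], 21, height), height, 21 * height)

    def test_vertical_root_arithmetic(self):
        m = measure_tooth(self._region(30), Point2D(50, 140), "lower",
                          CalibrationConfig(mm_per_px=0.1))
        assert m is not None
        assert m.root_length_px == pytest.approx(100.0)
        assert m.bl_percent == pytest.approx(30.0)
        assert m.max_bl_mm == pytest.approx(3.0)

    def test_normal_bone_allowance_filters_shallow_regions(self):
        # 15 px at 0.1 mm/px = 1.5 mm <= 2 mm: physiological, not reported
        assert measure_tooth(self._region(15), Point2D(50, 140), "lower",
                             CalibrationConfig(mm_per_px=0.1)) is None

    def test_oblique_root(self):
        m = measure_tooth(self._region(30), Point2D(80, 130), "lower",
                          CalibrationConfig(mm_per_px=0.1))
        assert m.root_length_px == pytest.approx(np.hypot(30, 90))
        assert m.bl_percent == pytest.approx(100 * 30 / np.hypot(30, 90), abs=1e-9)
        assert round(m.bl_percent, 2) == 31.62

    def test_zero_root_length_raises(self):
        with pytest.raises(ValueError, match="zero root length"):
            measure_tooth(self._region(30), Point2D(50, 40), "lower")

    def test_bl_percent_capped_at_100(self):
        m = measure_tooth(self._region(90), Point2D(50, 60), "lower",
                          CalibrationConfig(mm_per_px=0.1))
        assert m.bl_percent == 100.0


class TestInvariances:
    def _measure_mask(self, mask, apex, jaw="lower"):
        region = find_bl_regions(mask)[0]
        return measure_tooth(region, apex, jaw, CalibrationConfig(min_bl_mm=0.0))

    def test_translation_invariance(self):
        mask = _rect_mask((200, 200), (40, 69), (45, 55))
        m0 = self._measure_mask(mask, Point2D(50, 140))
        dx, dy = 17, 23
        mask2 = np.zeros_like(mask)
        mask2[40 + dy : 70 + dy, 45 + dx : 56 + dx] = 1
        m1 = self._measure_mask(mask2, Point2D(50 + dx, 140 + dy))
        assert m0.max_bl_px == m1.max_bl_px
        assert m0.root_length_px == pytest.approx(m1.root_length_px)
        assert m0.bl_percent == pytest.approx(m1.bl_percent)

    def test_horizontal_flip_invariance(self):
        mask = _rect_mask((200, 200), (40, 69), (45, 55))
        apex = Point2D(53, 140)
        m0 = self._measure_mask(mask, apex)
        flipped = mask[:, ::-1]
        apex_f = Point2D(mask.shape[1] - 1 - apex.x, apex.y)
        m1 = self._measure_mask(flipped, apex_f)
        assert m0.bl_percent == pytest.approx(m1.bl_percent)

    def test_bl_percent_strictly_increases_with_region_height(self):
        apex = Point2D(50, 150)
        previous = 0.0
        for h in (25, 30, 40, 55):
            mask = _rect_mask((200, 200), (40, 40 + h - 1), (45, 55))
            m = self._measure_mask(mask, apex)
            assert m.bl_percent > previous
            previous = m.bl_percent


class TestAssociation:
    def _region_at(self, x_mid, rid=0):
        return RegionMeasurement(rid, (x_mid - 10, 30, 21, 20), 20, 420)

    def test_two_teeth_pair_by_horizontal_distance(self):
        regions = [self._region_at(60, 0), self._region_at(200, 1)]
        apexes = [Point2D(62, 120), Point2D(205, 120)]
        pairs, un_r, un_a = associate_regions_to_apexes(regions, apexes, "lower")
        assert {(p[0].x_mid, p[1].x) for p in pairs} == {(60, 62), (200, 205)}
        assert un_r == [] and un_a == []

    def test_unpaired_region_reported(self):
        regions = [self._region_at(60)]
        pairs, un_r, un_a = associate_regions_to_apexes(regions, [], "lower")
        assert pairs == [] and len(un_r) == 1 and un_a == []

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_exhaustive_assignment(self, seed):
        """Greedy pairing equals the min-total-|dx| assignment on separated
        layouts (one apex near each tooth, as on a real radiograph)."""
        from itertools import permutations

        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 5))
        slots = np.sort(rng.choice(np.arange(30, 290, 10), n, replace=False))
        regions = [self._region_at(int(s), i) for i, s in enumerate(slots)]
        apexes = [Point2D(int(s + rng.integers(-4, 5)), 120) for s in slots]
        perm_apexes = [apexes[i] for i in rng.permutation(n)]
        pairs, _, _ = associate_regions_to_apexes(regions, perm_apexes, "lower")
        got = sum(abs(r.x_mid - a.x) for r, a in pairs)
        best = min(
            sum(abs(r.x_mid - a.x) for r, a in zip(regions, p))
            for p in permutations(perm_apexes)
        )
        assert got == pytest.approx(best)
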