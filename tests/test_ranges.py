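import numpy as np
import pytest

from maxsdm import (
    GridSpec,
    SuitabilityMap,
    area_report,
    binary_suitable,
    centroid,
    centroid_distance_km,
    centroid_track,
    change_map,
    classify,
    overlap,
)
from maxsdm.grids import cell_areas_map
from maxsdm.ranges import NODATA_CODE, percent_change


@pytest.fixture
def grid():
    return GridSpec(100.0, 30.0, 0.5, 6, 6)


def smap(grid, values):
    return SuitabilityMap(grid, np.asarray(values, dtype=float))


class TestClassify:
    @pytest.mark.parametrize(
        "p,code",
        [(0.19999, 0), (0.2, 1), (0.39999, 1), (0.4, 2), (0.6, 3), (0.95, 3)],
    )
    def test_left_closed_boundaries(self, grid, p, code):
        vals = np.full(grid.shape, p)
        cmap = classify(smap(grid, vals))
        assert cmap.codes[0, 0] == code

    def test_nodata_preserved(self, grid):
        vals = np.full(grid.shape, 0.5)
        vals[2, 2] = grid.nodata
        cmap = classify(smap(grid, vals))
        assert cmap.codes[2, 2] == NODATA_CODE

    def test_non_monotone_thresholds_rejected(self, grid):
        with pytest.raises(ValueError):
            classify(smap(grid, np.zeros(grid.shape)), (0.4, 0.2, 0.6))

    def test_binary_consistency_with_classes(self, grid):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, grid.shape)
        vals[1, 1] = grid.nodata
        m = smap(grid, vals)
        mask, valid = binary_suitable(m, 0.2)
        cmap = classify(m)
        np.testing.assert_array_equal(mask, (cmap.codes >= 1))
        assert not mask[1, 1] and not valid[1, 1]


class TestAreaReport:
    def test_total_is_sum_of_classes(self, grid):
        rng = np.random.default_rng(1)
        rep = area_report(classify(smap(grid, rng.uniform(0, 1, grid.shape))))
        assert rep.total == pytest.approx(
            rep.areas["low"] + rep.areas["moderate"] + rep.areas["extreme"]
        )

    def test_class_areas_partition_valid_area(self, grid):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 1, grid.shape)
        cmap = classify(smap(grid, vals))
        unsuitable = cell_areas_map(grid)[cmap.codes == 0].sum() / 1e4
        assert area_report(cmap).total + unsuitable == pytest.approx(
            cell_areas_map(grid).sum() / 1e4
        )

    def test_percent_change_from_full_precision(self):
        assert percent_change(14.92, 29.65) == pytest.approx(98.7265, abs=1e-3)
        assert percent_change(111.42, 133.66) == pytest.approx(19.9605, abs=1e-3)
        assert percent_change(5.0, 5.0) == 0.0
        assert percent_change(0.0, 3.0) is None  # undefined, never inf

    def test_baseline_change_wiring(self, grid):
        vals = np.full(grid.shape, 0.7)
        base = area_report(classify(smap(grid, vals)))
        doubled = np.full(grid.shape, 0.7)
        rep = area_report(classify(smap(grid, doubled)), baseline=base)
        assert rep.change_pct["extreme"] == pytest.approx(0.0)
        assert rep.change_pct["low"] == 0.0  # both zero -> 0, not undefined


class TestChangeMap:
    def test_identical_masks_no_gain_loss(self, grid):
        m = np.zeros(grid.shape, bool)
        m[1:3, 1:3] = True
        codes = change_map(m, m)
        assert not ((codes == 1) | (codes == 2)).any()
        assert (codes == 3).sum() == m.sum()

    def test_disjoint_masks(self, grid):
        a = np.zeros(grid.shape, bool)
        b = np.zeros(grid.shape, bool)
        a[0, :3] = True
        b[5, :4] = True
        codes = change_map(a, b)
        assert (codes == 1).sum() == 4 and (codes == 2).sum() == 3

    def test_gain_minus_loss_equals_net_area(self, grid):
        rng = np.random.default_rng(3)
        a = rng.uniform(size=grid.shape) > 0.5
        b = rng.uniform(size=grid.shape) > 0.5
        areas = cell_areas_map(grid)
        codes = change_map(a, b)
        net = areas[codes == 1].sum() - areas[codes == 2].sum()
        assert net == pytest.approx(areas[b].sum() - areas[a].sum())

    def test_shape_mismatch(self, grid):
        with pytest.raises(ValueError):
            change_map(np.zeros((2, 2), bool), np.zeros(grid.shape, bool))


class TestCentroid:
    def test_single_cell_is_its_center(self, grid):
        m = np.zeros(grid.shape, bool)
        m[2, 3] = True
        assert centroid(m, grid) == grid.cell_center(2, 3)

    def test_meridian_symmetry(self, grid):
        m = np.zeros(grid.shape, bool)
        m[2, 1] = m[2, 4] = True  # symmetric about the column-2/3 edge
        lon, _ = centroid(m, grid)
        assert lon == pytest.approx(
            (grid.cell_center(2, 1)[0] + grid.cell_center(2, 4)[0]) / 2
        )

    def test_two_equal_latitude_cells_average_longitude(self):
        g = GridSpec(95.0, 30.0, 5.0, 2, 4)
        m = np.zeros(g.shape, bool)
        m[0, 1] = m[0, 3] = True  # centers at lon 102.5 and 112.5
        lon, lat = centroid(m, g)
        assert lon == pytest.approx(107.5)
        assert lat == pytest.approx(g.cell_center(0, 0)[1])

    def test_empty_mask_rejected(self, grid):
        with pytest.raises(ValueError):
            centroid(np.zeros(grid.shape, bool), grid)

    def test_union_of_disjoint_masks_is_weighted_mean(self, grid):
        rng = np.random.default_rng(4)
        a = rng.uniform(size=grid.shape) > 0.7
        b = (~a) & (rng.uniform(size=grid.shape) > 0.7)
        areas = cell_areas_map(grid)
        ca, cb = centroid(a, grid), centroid(b, grid)
        cu = centroid(a | b, grid)
        wa, wb = areas[a].sum(), areas[b].sum()
        assert cu[0] == pytest.approx((ca[0] * wa + cb[0] * wb) / (wa + wb))
        assert cu[1] == pytest.approx((ca[1] * wa + cb[1] * wb) / (wa + wb))


class TestDistance:
    def test_identity_and_symmetry(self):
        a, b = (110.67, 26.74), (112.23, 27.65)
        assert centroid_distance_km(a, a) == 0.0
        assert centroid_distance_km(a, b) == centroid_distance_km(b, a)

    def test_one_degree_of_latitude(self):
        from maxsdm import EARTH_RADIUS_KM
        import math

        d = centroid_distance_km((0.0, 0.0), (0.0, 1.0))
        assert d == pytest.approx(EARTH_RADIUS_KM * math.pi / 180, rel=1e-12)

    def test_track_wiring(self, grid):
        m1 = np.zeros(grid.shape, bool)
        m2 = np.zeros(grid.shape, bool)
        m1[0, 0] = m2[5, 5] = True
        track = centroid_track([("now", m1), ("later", m2)], grid)
        assert len(track.points) == 2 and len(track.distances_km) == 1
        assert track.distances_km[0] > 0


class TestOverlap:
    def test_identical_masks_100_percent(self, grid):
        m = np.zeros(grid.shape, bool)
        m[1:4, 2:5] = True
        rep = overlap(m, m, grid)
        assert rep.percentage == pytest.approx(100.0)
        assert rep.intersection == pytest.approx(rep.area_a)

    def test_disjoint_masks_zero_percent(self, grid):
        a = np.zeros(grid.shape, bool)
        b = np.zeros(grid.shape, bool)
        a[0, 0] = b[5, 5] = True
        assert overlap(a, b, grid).percentage == 0.0

    def test_intersection_bounded_by_smaller_range(self, grid):
        rng = np.random.default_rng(5)
        a = rng.uniform(size=grid.shape) > 0.4
        b = rng.uniform(size=grid.shape) > 0.4
        rep = overlap(a, b, grid)
        assert rep.intersection <= min(rep.area_a, rep.area_b) + 1e-12
        assert 0.0 <= rep.percentage <= 100.0
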