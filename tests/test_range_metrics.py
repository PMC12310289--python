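"""Decoupled scenario inputs, binary maps, areas, centroids, shifts."""

import math

import numpy as np
import pytest

import rangeshift as rs
from rangeshift.grid import CLIMATE_LAYERS, LANDCOVER_LAYERS, EARTH_RADIUS_KM, ScenarioSpec
from rangeshift.range_metrics import SuitabilityMap


def suit_map(values, origin=(0.0, 4.0), res_arcmin=60.0, mask=None):
    values = np.asarray(values, float)
    if mask is None:
        mask = np.zeros(values.shape, bool)
    return SuitabilityMap(origin[0], origin[1], res_arcmin, values, mask, "s")


class TestDecoupledInputs:
    def test_identical_future_is_identity(self, env_small):
        scen = ScenarioSpec("same", "none", env_small.copy())
        for mode in ("both", "clim", "land"):
            out = rs.make_decoupled_inputs(env_small, scen, mode)
            for name in env_small.layers:
                np.testing.assert_array_equal(out.layers[name],
                                              env_small.layers[name])

    def test_land_mode_keeps_climate_bit_identical(self, env_small):
        scen = rs.generate_future(env_small, {"tmax": 3.0, "crop": 0.5})
        out = rs.make_decoupled_inputs(env_small, scen, "land")
        for name in CLIMATE_LAYERS:
            assert np.array_equal(out.layers[name], env_small.layers[name])
        assert not np.array_equal(out.layers["crop"], env_small.layers["crop"])

    def test_clim_plus_land_reconstructs_both(self, env_small):
        scen = rs.generate_future(env_small, {"tmax": 3.0, "pan": 0.9, "crop": 0.5})
        both = rs.make_decoupled_inputs(env_small, scen, "both")
        clim = rs.make_decoupled_inputs(env_small, scen, "clim")
        land = rs.make_decoupled_inputs(env_small, scen, "land")
        for name in CLIMATE_LAYERS:
            np.testing.assert_array_equal(both.layers[name], clim.layers[name])
        for name in LANDCOVER_LAYERS:
            np.testing.assert_array_equal(both.layers[name], land.layers[name])

    def test_misalignment_rejected(self, env_small):
        other = env_small.copy()
        other.origin_lon += 1.0
        with pytest.raises(ValueError, match="misaligned"):
            rs.make_decoupled_inputs(env_small, ScenarioSpec("x", "y", other), "both")


class TestBinarize:
    def test_threshold_zero_selects_everything(self):
        m = suit_map(np.random.default_rng(0).random((4, 5)))
        assert rs.binarize(m, 0.0).values.all()

    def test_threshold_above_max_selects_nothing(self):
        m = suit_map(np.full((4, 5), 0.7))
        assert not rs.binarize(m, 0.9).values.any()

    def test_count_matches_full_scan(self):
        vals = np.random.default_rng(1).random((10, 12))
        m = suit_map(vals)
        b = rs.binarize(m, 0.35)
        manual = sum(vals[r, c] >= 0.35 for r in range(10) for c in range(12))
        assert b.values.sum() == manual
        assert b.threshold == 0.35


class TestAreaOfHabitat:
    def test_empty_map_zero(self):
        b = rs.binarize(suit_map(np.zeros((3, 3))), 0.5)
        assert rs.area_of_habitat(b, np.ones(3)) == 0.0

    def test_single_cell_gives_row_area(self):
        vals = np.zeros((3, 3))
        vals[1, 2] = 1.0
        b = rs.binarize(suit_map(vals), 0.5)
        areas = np.array([10.0, 20.0, 30.0])
        assert rs.area_of_habitat(b, areas) == 20.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        vals = rng.random((20, 15))
        m = suit_map(vals, origin=(0.0, 20.0))
        g = rs.EnvGrid(0.0, 20.0, 60.0, {"v": vals})
        areas = rs.cell_areas_km2(g)
        b = rs.binarize(m, 0.5)
        manual = sum(areas[r] for r in range(20) for c in range(15)
                     if vals[r, c] >= 0.5)
        assert rs.area_of_habitat(b, areas) == pytest.approx(manual, rel=1e-9)

    def test_monotone_in_threshold(self):
        vals = np.random.default_rng(3).random((10, 10))
        m = suit_map(vals)
        areas = np.ones(10)
        prev = math.inf
        for thr in (0.1, 0.3, 0.5, 0.7, 0.9):
            a = rs.area_of_habitat(rs.binarize(m, thr), areas)
            assert a <= prev
            prev = a


class TestWeightedCentroid:
    def test_uniform_suitability_gives_geometric_center(self):
        m = suit_map(np.full((4, 6), 0.42), origin=(10.0, 50.0))
        lon, lat = rs.weighted_centroid(m)
        assert lon == pytest.approx(10.0 + 3.0)
        assert lat == pytest.approx(50.0 - 2.0)

    def test_point_mass_gives_that_cell_center(self):
        vals = np.zeros((5, 5))
        vals[2, 3] = 0.8
        m = suit_map(vals)
        lon, lat = rs.weighted_centroid(m)
        assert lon == pytest.approx(3.5)
        assert lat == pytest.approx(4.0 - 2.5)

    def test_matches_brute_force_weighted_mean(self):
        rng = np.random.default_rng(4)
        vals = rng.random((8, 9))
        m = suit_map(vals, origin=(-3.0, 45.0), res_arcmin=5.0)
        lon, lat = rs.weighted_centroid(m)
        num_lon = num_lat = den = 0.0
        for r in range(8):
            for c in range(9):
                w = vals[r, c]
                num_lon += w * (-3.0 + (c + 0.5) * 5 / 60)
                num_lat += w * (45.0 - (r + 0.5) * 5 / 60)
                den += w
        assert lon == pytest.approx(num_lon / den, abs=1e-12)
        assert lat == pytest.approx(num_lat / den, abs=1e-12)

    def test_centroid_inside_bounding_box_of_mass(self):
        vals = np.zeros((6, 6))
        vals[1:3, 4:6] = 0.5
        lon, lat = rs.weighted_centroid(suit_map(vals, origin=(0.0, 6.0)))
        assert 4.0 <= lon <= 6.0
        assert 3.0 <= lat <= 5.0

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            rs.weighted_centroid(suit_map(np.zeros((3, 3))))


class TestShiftAndChange:
    def test_one_degree_longitude_equator(self):
        expected = 2 * math.pi * EARTH_RADIUS_KM / 360
        assert rs.shift_km((0.0, 0.0), (1.0, 0.0)) == pytest.approx(expected, rel=1e-9)

    def test_zero_and_symmetry(self):
        assert rs.shift_km((2.0, 41.0), (2.0, 41.0)) == 0.0
        assert rs.shift_km((1.0, 40.0), (3.0, 42.0)) == pytest.approx(
            rs.shift_km((3.0, 42.0), (1.0, 40.0)))

    @pytest.mark.parametrize("future,current,expected",
                             [(100.0, 100.0, 0.0), (50.0, 100.0, -50.0),
                              (0.0, 100.0, -100.0)])
    def test_percent_change(self, future, current, expected):
        assert rs.percent_change(future, current) == expected

    def test_percent_change_zero_current_rejected(self):
        with pytest.raises(ValueError):
            rs.percent_change(10.0, 0.0)


class TestRestrictToOccupied:
    def test_full_occupancy_is_identity(self):
        vals = np.random.default_rng(5).random((4, 4))
        m = suit_map(vals)
        all_cells = {(r, c) for r in range(4) for c in range(4)}
        out = rs.restrict_to_occupied(m, all_cells)
        assert rs.weighted_centroid(out) == rs.weighted_centroid(m)

    def test_single_cell_centroid(self):
        vals = 0.05 + 0.9 * np.random.default_rng(6).random((4, 4))
        out = rs.restrict_to_occupied(suit_map(vals), {(1, 1)})
        lon, lat = rs.weighted_centroid(out)
        assert (lon, lat) == (pytest.approx(1.5), pytest.approx(4.0 - 1.5))

    def test_restricted_area_never_larger(self):
        vals = np.random.default_rng(7).random((6, 6))
        m = suit_map(vals)
        areas = np.ones(6)
        out = rs.restrict_to_occupied(m, {(0, 0), (2, 3), (5, 5)})
        a_full = rs.area_of_habitat(rs.binarize(m, 0.3), areas)
        a_restr = rs.area_of_habitat(rs.binarize(out, 0.3), areas)
        assert a_restr <= a_full

    def test_empty_intersection_rejected(self):
        m = suit_map(np.ones((3, 3)))
        with pytest.raises(ValueError, match="empty"):
            rs.restrict_to_occupied(m, {(99, 99)})
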