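"""Predictor-layer construction: each operation against a direct oracle."""

import numpy as np
import pytest
import shapely
from shapely.geometry import LineString, Point, box

from peatfire import features as F
from peatfire.exceptions import (
    ExtentError,
    GeometryError,
    MappingError,
    NormalizationError,
)
from peatfire.grids import GridSpec


def lc_map(classes, grid, year):
    return F.LandCoverMap(grid=grid, classes=np.asarray(classes, dtype=np.uint8),
                          map_year=year)


@pytest.fixture()
def grid5():
    return GridSpec(0, 5 * 250.0, 250.0, 5, 5)


class TestRegroupAndExpand:
    def test_identity_regroup(self, grid5):
        raw = np.full((5, 5), 3)
        out = F.regroup_landcover(raw, {3: "swamp_scrub"}, grid5, 2000)
        assert (out.classes == F.LC_CLASSES["swamp_scrub"]).all()

    def test_pixel_counts_preserved_through_merge(self, grid5):
        raw = np.array([[10] * 5] * 3 + [[11] * 5] * 2)
        out = F.regroup_landcover(raw, {10: "dry_forest", 11: "dry_forest"},
                                  grid5, 2000)
        assert (out.classes == F.LC_CLASSES["dry_forest"]).sum() == 25

    def test_unmapped_class_rejected(self, grid5):
        raw = np.full((5, 5), 99)
        with pytest.raises(MappingError, match="99"):
            F.regroup_landcover(raw, {1: "riceland"}, grid5, 2000)

    def test_binary_expand_partition_of_unity(self, grid5, rng):
        classes = rng.integers(1, 9, size=(5, 5))
        out = F.binary_expand(lc_map(classes, grid5, 2000))
        assert len(out) == 8
        total = np.sum(list(out.values()), axis=0)
        assert (total == 1).all()

    def test_binary_expand_round_trip(self, grid5, rng):
        classes = rng.integers(1, 9, size=(5, 5))
        out = F.binary_expand(lc_map(classes, grid5, 2000))
        stack = np.stack([out[f"lc_{n}"] for n in F.LC_CLASSES], axis=0)
        recon = np.argmax(stack, axis=0) + 1
        assert (recon == classes).all()


class TestClearanceIndex:
    MAP_DATES = (1996, 2000, 2003, 2006, 2009, 2011, 2012, 2013, 2015)

    def series(self, grid5, forest_until, cleared_from):
        """Uniform rasters: forest through `forest_until`, cleared after."""
        maps = []
        for d in self.MAP_DATES:
            code = "swamp_forest" if d <= forest_until else "swamp_scrub"
            maps.append(lc_map(np.full((5, 5), F.LC_CLASSES[code]), grid5, d))
        return maps

    def test_worked_example_minus_ten_then_minus_four(self, grid5):
        """Clearing between the 2000 and 2003 maps: index -10 at 2003,
        decayed one step per map iteration to -4 by 2015."""
        maps = self.series(grid5, forest_until=2000, cleared_from=2003)
        at_2003 = F.forest_clearance_index(maps, target_map_year=2003)
        assert (at_2003.values == -10).all()
        at_2015 = F.forest_clearance_index(maps, target_map_year=2015)
        assert (at_2015.values == -4).all()

    def test_no_transition_stays_zero(self, grid5):
        maps = [lc_map(np.full((5, 5), F.LC_CLASSES["riceland"]), grid5, d)
                for d in self.MAP_DATES]
        for target in (2003, 2011, 2015):
            assert (F.forest_clearance_index(maps, target).values == 0).all()

    @pytest.mark.parametrize("m_after", range(0, 13))
    def test_gain_decay_hand_stepped(self, grid5, m_after):
        """Regrowth then m stable maps: index max(10 - m, 0)."""
        dates = list(range(2000, 2000 + m_after + 2))
        maps = [lc_map(np.full((5, 5), F.LC_CLASSES["scrub_bare"]), grid5,
                       dates[0])]
        for d in dates[1:]:
            maps.append(lc_map(np.full((5, 5), F.LC_CLASSES["dry_forest"]),
                               grid5, d))
        out = F.forest_clearance_index(maps, target_map_year=dates[-1])
        assert (out.values == max(10 - m_after, 0)).all()

    def test_new_transition_resets_index(self, grid5):
        codes = ["dry_forest", "swamp_scrub", "swamp_scrub", "dry_forest"]
        maps = [lc_map(np.full((5, 5), F.LC_CLASSES[c]), grid5, 2000 + i)
                for i, c in enumerate(codes)]
        out = F.forest_clearance_index(maps, target_map_year=2003)
        assert (out.values == 10).all()

    def test_matches_scalar_replay_oracle(self, grid5, rng):
        """Vectorized index equals an independent per-pixel scalar replay."""
        n_maps = 7
        forest_series = rng.uniform(size=(n_maps, 5, 5)) < 0.5
        maps = [lc_map(np.where(forest_series[i], F.LC_CLASSES["dry_forest"],
                                F.LC_CLASSES["riceland"]), grid5, 2000 + i)
                for i in range(n_maps)]
        got = F.forest_clearance_index(maps, target_map_year=2000 + n_maps - 1)

        def replay(states):
            idx = 0
            for prev, cur in zip(states[:-1], states[1:]):
                idx -= np.sign(idx)
                if prev and not cur:
                    idx = -10
                elif cur and not prev:
                    idx = 10
            return idx

        for r in range(5):
            for c in range(5):
                assert got.values[r, c] == replay(forest_series[:, r, c])

    def test_unordered_maps_rejected(self, grid5):
        maps = self.series(grid5, 2000, 2003)
        with pytest.raises(ValueError):
            F.forest_clearance_index(maps[::-1], 2015)


class TestGapFill:
    def test_identity_without_missing(self, rng):
        x = rng.normal(size=(8, 8))
        assert np.array_equal(F.gap_fill(x), x)

    def test_single_hole_mean_of_24_neighbours(self, rng):
        x = rng.normal(size=(9, 9))
        x[4, 4] = np.nan
        window = x[2:7, 2:7]
        expect = np.nanmean(window)
        assert F.gap_fill(x)[4, 4] == pytest.approx(expect)

    def test_corner_hole_truncated_window(self, rng):
        x = rng.normal(size=(6, 6))
        x[0, 0] = np.nan
        expect = np.nanmean(x[:3, :3])
        assert F.gap_fill(x)[0, 0] == pytest.approx(expect)

    def test_isolated_all_missing_window_stays_nodata(self):
        x = np.full((11, 11), np.nan)
        x[0, 0] = 1.0
        out = F.gap_fill(x)
        assert np.isnan(out[10, 10])

    def test_idempotent(self, rng):
        x = rng.normal(size=(10, 10))
        x[rng.uniform(size=(10, 10)) < 0.2] = np.nan
        once = F.gap_fill(x)
        assert np.allclose(F.gap_fill(once), once, equal_nan=True)


class TestEtPetRatio:
    def test_equal_inputs_give_one(self):
        x = np.full((4, 4), 55.0)
        assert (F.et_pet_ratio(x, x) == 1.0).all()

    def test_half_ratio_and_zero_pet(self):
        et = np.full((2, 2), 30.0)
        pet = np.array([[60.0, 60.0], [0.0, -5.0]])
        out = F.et_pet_ratio(et, pet)
        assert out[0, 0] == 0.5
        assert np.isnan(out[1, 0]) and np.isnan(out[1, 1])


class TestReferenceNormalization:
    def test_uniform_raster_whole_reference(self, grid5):
        x = np.full((5, 5), 7.0)
        out = F.normalize_by_reference(x, grid5.bounds_polygon, grid5)
        assert np.allclose(out, 1.0)

    def test_ratio_against_reference_patch(self, grid5):
        x = np.full((5, 5), 2.0)
        x[:, 3:] = 4.0
        ref = box(3 * 250.0, 0, 5 * 250.0, 5 * 250.0)  # the value-4 strip
        out = F.normalize_by_reference(x, ref, grid5)
        assert np.allclose(out[:, :3], 0.5)
        xm, ym = grid5.center_mesh()
        inside = shapely.contains_xy(ref, xm.ravel(), ym.ravel()).reshape(5, 5)
        assert out[inside].mean() == pytest.approx(1.0)

    def test_zero_reference_mean_rejected(self, grid5):
        x = np.zeros((5, 5))
        with pytest.raises(NormalizationError):
            F.normalize_by_reference(x, grid5.bounds_polygon, grid5)


class TestInterpolatePrecip:
    def setup_method(self):
        self.coarse = GridSpec(0, 4000, 1000, 4, 4)
        self.fine = GridSpec(0, 4000, 250, 16, 16)

    def test_constant_field_preserved(self):
        out = F.interpolate_precip(np.full((4, 4), 3.5), self.coarse, self.fine)
        assert np.allclose(out, 3.5)

    def test_midpoint_between_four_centers(self):
        vals = np.array([[0.0, 0.0], [10.0, 10.0]])
        coarse = GridSpec(0, 2000, 1000, 2, 2)
        # single-cell fine grid whose centre (1000, 1000) is equidistant
        # from all four coarse centres valued {0, 0, 10, 10}
        fine = GridSpec(750, 1250, 500, 1, 1)
        out = F.interpolate_precip(vals, coarse, fine)
        assert out[0, 0] == pytest.approx(5.0)

    def test_reproduces_linear_ramp(self):
        xs = self.coarse.x_centers()
        ramp = np.tile(0.01 * xs, (4, 1))
        out = F.interpolate_precip(ramp, self.coarse, self.fine)
        xm, _ = self.fine.center_mesh()
        inner = (xm >= xs[0]) & (xm <= xs[-1])  # clamped margin excluded
        assert np.allclose(out[inner], 0.01 * xm[inner])

    def test_fine_grid_outside_extent_rejected(self):
        far = GridSpec(-5000, 4000, 250, 16, 16)
        with pytest.raises(ExtentError):
            F.interpolate_precip(np.zeros((4, 4)), self.coarse, far)


class TestDistanceRaster:
    def test_point_on_canal_is_zero(self):
        grid = GridSpec(0, 1000, 250, 4, 4)
        canal = LineString([(0, 875), (1000, 875)])  # through row-0 centres
        out = F.distance_raster([canal], grid)
        assert np.allclose(out[0, :], 0.0)

    def test_single_point_pythagoras(self):
        grid = GridSpec(0, 1000, 250, 4, 4)
        p = Point(125, 875)  # centre of cell (0, 0)
        out = F.distance_raster([p], grid)
        xm, ym = grid.center_mesh()
        expect = np.hypot(xm - 125, ym - 875)
        assert np.allclose(out, expect)

    def test_matches_brute_force_over_segments(self, rng):
        grid = GridSpec(0, 10000, 250, 40, 40)
        segs = [LineString(rng.uniform(0, 10000, size=(2, 2)))
                for _ in range(20)]
        out = F.distance_raster(segs, grid)
        xm, ym = grid.center_mesh()
        pts = shapely.points(xm.ravel(), ym.ravel())
        brute = np.min([shapely.distance(pts, s) for s in segs], axis=0)
        assert np.allclose(out.ravel(), brute, atol=1e-6)

    def test_empty_features_rejected(self, grid5):
        with pytest.raises(GeometryError):
            F.distance_raster([], grid5)


class TestTerrain:
    def test_flat_surface(self, grid5):
        slope, aspect = F.terrain_derivatives(np.full((5, 5), 12.0), grid5)
        assert np.allclose(slope, 0.0)
        assert np.isnan(aspect).all()

    def test_unit_plane_east_rise(self, grid5):
        xm, _ = grid5.center_mesh()
        slope, aspect = F.terrain_derivatives(xm.astype(float), grid5)
        assert np.allclose(slope, 45.0)
        assert np.allclose(aspect, 270.0)  # downslope faces west

    def test_north_rise_faces_south(self, grid5):
        _, ym = grid5.center_mesh()
        slope, aspect = F.terrain_derivatives(0.5 * ym, grid5)
        assert np.allclose(aspect, 180.0)

    def test_translation_invariance(self, grid5, rng):
        z = rng.normal(size=(5, 5)) * 5
        s1, _ = F.terrain_derivatives(z, grid5)
        s2, _ = F.terrain_derivatives(z + 100.0, grid5)
        assert np.allclose(s1, s2)

    def test_too_small_raster_rejected(self, grid5):
        with pytest.raises(ValueError):
            F.terrain_derivatives(np.zeros((2, 5)), grid5)


class TestOniLayer:
    def test_constant_layer(self, grid5):
        out = F.oni_layer({2015: 2.0}, 2015, grid5)
        assert (out == 2.0).all() and out.var() == 0.0

    def test_missing_year_rejected(self, grid5):
        with pytest.raises(KeyError):
            F.oni_layer({2015: 2.0}, 2014, grid5)


class TestSeasonal:
    def test_pre_season_mean(self):
        monthly = {m: np.full((3, 3), float(v))
                   for m, v in zip((5, 6, 7), (1, 2, 3))}
        out = F.seasonal_aggregate(monthly, F.PRE_FIRE_MONTHS)
        assert np.allclose(out, 2.0)

    def test_delta_august_minus_preseason(self):
        monthly = {8: np.full((3, 3), 5.0)}
        out = F.delta_aug_prefs(monthly, np.full((3, 3), 2.0))
        assert np.allclose(out, 3.0)

    def test_missing_month_named(self):
        with pytest.raises(ValueError, match=r"\[6"):
            F.seasonal_aggregate({5: np.zeros((2, 2)), 7: np.zeros((2, 2))},
                                 F.PRE_FIRE_MONTHS)


class TestCrossYearNormalize:
    def test_pooled_range_endpoints(self):
        stacks = {2015: {"v": np.array([[0.0, 10.0]])},
                  2016: {"v": np.array([[5.0, 20.0]])}}
        normed, params = F.cross_year_normalize(stacks)
        assert params["v"].vmin == 0.0 and params["v"].vmax == 20.0
        assert normed[2015]["v"][0, 1] == pytest.approx(0.5)
        assert normed[2015]["v"][0, 0] == 0.0
        assert normed[2016]["v"][0, 1] == 1.0

    def test_round_trip(self, rng):
        stacks = {y: {"v": rng.normal(size=(4, 4))} for y in (2015, 2016)}
        normed, params = F.cross_year_normalize(stacks)
        p = params["v"]
        back = normed[2015]["v"] * (p.vmax - p.vmin) + p.vmin
        assert np.allclose(back, stacks[2015]["v"], atol=1e-9)

    def test_constant_variable_rejected_unless_passthrough(self):
        stacks = {2015: {"v": np.ones((2, 2))}}
        with pytest.raises(NormalizationError):
            F.cross_year_normalize(stacks)
        normed, _ = F.cross_year_normalize(stacks, on_constant="passthrough")
        assert np.allclose(normed[2015]["v"], 1.0)

    def test_params_json_round_trip(self, tmp_path):
        params = {"v": F.NormalizationParams("v", -2.0, 3.0)}
        path = tmp_path / "norm.json"
        F.save_normalization(path, params)
        back = F.load_normalization(path)
        assert back["v"] == params["v"]
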