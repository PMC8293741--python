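"""Threat-index scoring, summation, classification and sensitivity."""

import numpy as np
import pytest
from shapely.geometry import LineString, box

from threatscape.grid import GridSpec, PolygonSet, RasterLayer
from threatscape.synthetic import SyntheticConfig, gen_threat_factors
from threatscape.threat import (
    SCENARIOS,
    classify_index,
    compute_threat_index,
    mean_future,
    score_burn_trend,
    score_climate_delta,
    score_overexploitation,
    score_population,
    score_roads,
    score_threshold_layer,
    sensitivity_compare,
    sum_index,
)


def one_cell_layer(value: float, name: str = "x") -> RasterLayer:
    return RasterLayer(GridSpec(1, 1, 0.0, 5000.0, 5000.0), np.array([[value]]), name=name)


class TestScenarios:
    def test_reference_parameter_bundle(self):
        ref = SCENARIOS["reference"]
        assert (
            ref.pop_saturation, ref.crop_cutoff, ref.road_buffer_km, ref.overexploit_margin,
            ref.treeloss_cutoff, ref.burn_buffer_km, ref.temp_saturation_C, ref.precip_saturation_mm,
        ) == (1000.0, 0.20, 20.0, 0.0, 0.20, 5.0, 2.0, 200.0)

    def test_highest_and_lowest_bundles(self):
        hi, lo = SCENARIOS["highest"], SCENARIOS["lowest"]
        assert (hi.pop_saturation, hi.crop_cutoff, hi.road_buffer_km, hi.overexploit_margin,
                hi.treeloss_cutoff, hi.burn_buffer_km, hi.temp_saturation_C, hi.precip_saturation_mm
                ) == (800.0, 0.15, 25.0, -0.10, 0.15, 10.0, 1.5, 150.0)
        assert (lo.pop_saturation, lo.crop_cutoff, lo.road_buffer_km, lo.overexploit_margin,
                lo.treeloss_cutoff, lo.burn_buffer_km, lo.temp_saturation_C, lo.precip_saturation_mm
                ) == (1200.0, 0.25, 15.0, +0.10, 0.25, 0.0, 2.5, 250.0)


class TestPopulationScore:
    def test_saturation_density_scores_exactly_10(self):
        out = score_population(one_cell_layer(1000.0), saturation=1000.0)
        assert out.values[0, 0] == pytest.approx(10.0, abs=1e-12)

    def test_zero_density_scores_zero(self):
        assert score_population(one_cell_layer(0.0)).values[0, 0] == 0.0

    def test_direct_formula_evaluation(self):
        # density 99: (10/log10(1001)) * log10(100) = 6.666...
        out = score_population(one_cell_layer(99.0), saturation=1000.0)
        expected = 10.0 / np.log10(1001.0) * 2.0
        assert out.values[0, 0] == pytest.approx(expected)
        assert out.values[0, 0] == pytest.approx(6.666, abs=5e-3)

    def test_saturates_above_and_increases_below(self):
        grid = GridSpec(1, 4, 0.0, 5000.0, 5000.0)
        lay = RasterLayer(grid, np.array([[10.0, 100.0, 999.0, 5000.0]]))
        out = score_population(lay, saturation=1000.0).values[0]
        assert out[0] < out[1] < out[2] < 10.0
        assert out[3] == 10.0

    def test_negative_density_errors(self):
        with pytest.raises(ValueError):
            score_population(one_cell_layer(-1.0))


class TestThresholdScore:
    @pytest.mark.parametrize("frac,expected", [(0.20, 10.0), (0.19, 0.0), (0.0, 0.0), (1.0, 10.0)])
    def test_inclusive_cutoff(self, frac, expected):
        assert score_threshold_layer(one_cell_layer(frac), 0.20).values[0, 0] == expected

    def test_bad_cutoff_errors(self):
        with pytest.raises(ValueError):
            score_threshold_layer(one_cell_layer(0.5), 1.5)


class TestRoadScore:
    def test_band_matches_distance_to_segment_oracle(self):
        grid = GridSpec(9, 9, 0.0, 45_000.0, 5000.0)
        road = LineString([(0.0, 22_500.0), (45_000.0, 22_500.0)])  # horizontal, through row 4
        out = score_roads([road], grid, buffer_km=10.0)
        cx, cy = grid.cell_centers()
        for r in range(9):
            for c in range(9):
                # oracle: distance from the cell center to the road centerline,
                # through the rasterized-road cell centers the buffer grows from
                d_direct = road.distance(__import__("shapely").points(cx[r, c], cy[r, c]))
                if d_direct <= 2500.0:  # cell carries the road itself
                    assert out.values[r, c] == 10.0
        # band half-width 10 km around row 4 -> rows 2..6 inclusive
        assert np.all(out.values[2:7, :] == 10.0)
        assert np.all(out.values[[0, 1, 7, 8], :] == 0.0)

    def test_zero_buffer_marks_only_road_cells(self):
        grid = GridSpec(5, 5, 0.0, 25_000.0, 5000.0)
        road = LineString([(0.0, 12_500.0), (25_000.0, 12_500.0)])
        out = score_roads([road], grid, buffer_km=0.0)
        assert np.all(out.values[2, :] == 10.0)
        assert out.values.sum() == 5 * 10.0

    def test_scenario_widths_are_nested(self):
        grid = GridSpec(15, 15, 0.0, 75_000.0, 5000.0)
        road = LineString([(0.0, 37_500.0), (75_000.0, 37_500.0)])
        bands = {km: score_roads([road], grid, buffer_km=km).values for km in (15.0, 20.0, 25.0)}
        assert np.all(bands[20.0][bands[15.0] == 10.0] == 10.0)
        assert np.all(bands[25.0][bands[20.0] == 10.0] == 10.0)
        assert bands[25.0].sum() > bands[20.0].sum() > bands[15.0].sum()

    def test_empty_road_set_warns_all_zero(self, grid10):
        with pytest.warns(UserWarning, match="empty road"):
            out = score_roads([], grid10, buffer_km=20.0)
        assert not out.values.any()


class TestOverexploitationScore:
    def provinces(self, licensed, adequate):
        return PolygonSet([("p", box(0.0, 0.0, 5000.0, 5000.0), {
            "licensed_volume": licensed, "adequate_volume": adequate})])

    def test_licensed_above_adequate_scores_10(self):
        grid = GridSpec(1, 1, 0.0, 5000.0, 5000.0)
        out = score_overexploitation(self.provinces(110.0, 100.0), grid, margin=0.0)
        assert out.values[0, 0] == 10.0

    def test_equal_volumes_score_zero_strict_inequality(self):
        grid = GridSpec(1, 1, 0.0, 5000.0, 5000.0)
        out = score_overexploitation(self.provinces(100.0, 100.0), grid, margin=0.0)
        assert out.values[0, 0] == 0.0

    def test_negative_margin_lowers_the_bar(self):
        grid = GridSpec(1, 1, 0.0, 5000.0, 5000.0)
        out = score_overexploitation(self.provinces(95.0, 100.0), grid, margin=-0.10)
        assert out.values[0, 0] == 10.0  # bar becomes 90

    def test_missing_volume_errors(self):
        grid = GridSpec(1, 1, 0.0, 5000.0, 5000.0)
        polys = PolygonSet([("p", box(0, 0, 5000, 5000), {"licensed_volume": 1.0})])
        with pytest.raises(KeyError):
            score_overexploitation(polys, grid)


class TestBurnTrendScore:
    def test_zero_buffer_keeps_support(self, grid10):
        vals = np.zeros(grid10.shape)
        vals[4, 4] = 1.0
        out = score_burn_trend(RasterLayer(grid10, vals), buffer_km=0.0)
        assert np.array_equal(out.values, vals * 10.0)

    def test_5km_buffer_adds_one_ring_on_5km_grid(self, grid10):
        vals = np.zeros(grid10.shape)
        vals[4, 4] = 1.0
        out = score_burn_trend(RasterLayer(grid10, vals), buffer_km=5.0)
        assert out.values.sum() == 5 * 10.0  # center + orthogonal neighbours at exactly 5 km

    def test_all_zero_trend(self, grid10):
        out = score_burn_trend(RasterLayer(grid10, np.zeros(grid10.shape)), buffer_km=10.0)
        assert not out.values.any()

    def test_non_binary_errors(self, grid10):
        with pytest.raises(ValueError):
            score_burn_trend(RasterLayer(grid10, np.full(grid10.shape, 0.5)), 5.0)


class TestClimateScore:
    def test_temperature_saturation_at_2C(self):
        out = score_climate_delta(one_cell_layer(20.0), one_cell_layer(22.0), saturation=2.0)
        assert out.values[0, 0] == pytest.approx(10.0)

    def test_zero_amplitude_scores_zero(self):
        out = score_climate_delta(one_cell_layer(20.0), one_cell_layer(20.0), saturation=2.0)
        assert out.values[0, 0] == 0.0

    def test_precipitation_minus_100mm_scores_5(self):
        out = score_climate_delta(one_cell_layer(1000.0), one_cell_layer(900.0), saturation=200.0)
        assert out.values[0, 0] == pytest.approx(5.0)

    def test_grid_mismatch_errors(self):
        other = RasterLayer(GridSpec(2, 2, 0.0, 10_000.0, 5000.0), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            score_climate_delta(one_cell_layer(0.0), other, 2.0)


class TestMeanFuture:
    def test_single_layer_is_itself(self, rng, grid10):
        lay = RasterLayer(grid10, rng.normal(size=grid10.shape))
        assert np.array_equal(mean_future([lay]).values, lay.values)

    def test_cellwise_mean(self, grid10, constant_layer):
        out = mean_future([constant_layer(1.0), constant_layer(3.0)])
        assert np.allclose(out.values, 2.0)

    def test_random_layers_match_numpy_mean(self, rng, grid10):
        layers = [RasterLayer(grid10, rng.normal(size=grid10.shape)) for _ in range(8)]
        out = mean_future(layers)
        assert np.allclose(out.values, np.mean([l.values for l in layers], axis=0))

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            mean_future([])


def eight_layers(grid, value):
    names = ["a", "b", "c", "d", "e", "f", "g", "h"]
    return {n: RasterLayer(grid, np.full(grid.shape, value), name=n) for n in names}


class TestSumIndex:
    def test_all_max_sums_to_80(self, grid10, constant_layer):
        out = sum_index(eight_layers(grid10, 10.0), constant_layer(0.0))
        assert np.all(out.values == 80.0)

    def test_all_zero_sums_to_zero(self, grid10, constant_layer):
        out = sum_index(eight_layers(grid10, 0.0), constant_layer(0.0))
        assert np.all(out.values == 0.0)

    def test_mixed_layers_sum(self, grid10, constant_layer):
        layers = eight_layers(grid10, 10.0)
        for n in ("e", "f", "g", "h"):
            layers[n] = constant_layer(0.0)
        out = sum_index(layers, constant_layer(0.0))
        assert np.all(out.values == 40.0)

    def test_missing_score_counts_as_zero(self, grid10, constant_layer):
        layers = eight_layers(grid10, 5.0)
        vals = layers["a"].values.copy()
        vals[0, 0] = np.nan
        layers["a"] = RasterLayer(grid10, vals, name="a")
        out = sum_index(layers, constant_layer(0.0))
        assert out.values[0, 0] == 35.0
        assert out.values[5, 5] == 40.0

    def test_urban_cells_masked_after_sum(self, grid10, constant_layer):
        urban = np.zeros(grid10.shape)
        urban[1, 1] = 1.0
        out = sum_index(eight_layers(grid10, 1.0), RasterLayer(grid10, urban))
        assert np.isnan(out.values[1, 1])
        assert out.values[0, 0] == 8.0

    def test_wrong_layer_count_errors(self, grid10, constant_layer):
        layers = eight_layers(grid10, 1.0)
        layers.pop("h")
        with pytest.raises(ValueError, match="8"):
            sum_index(layers, constant_layer(0.0))

    def test_out_of_range_score_errors(self, grid10, constant_layer):
        layers = eight_layers(grid10, 1.0)
        layers["a"] = constant_layer(11.0, name="a")
        with pytest.raises(ValueError, match="0, 10"):
            sum_index(layers, constant_layer(0.0))


class TestClassifyIndex:
    @pytest.mark.parametrize(
        "value,code",
        [(0.0, 1), (7.2, 1), (19.999, 1), (20.0, 2), (39.999, 2), (40.0, 3),
         (60.0, 3), (60.001, 4), (73.6, 4), (80.0, 4)],
    )
    def test_boundary_convention(self, value, code):
        out = classify_index(one_cell_layer(value))
        assert out.values[0, 0] == code

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            classify_index(one_cell_layer(81.0))

    def test_every_cell_gets_exactly_one_class(self, rng, grid10):
        idx = RasterLayer(grid10, rng.uniform(0, 80, size=grid10.shape))
        out = classify_index(idx)
        assert np.isin(out.values, [1, 2, 3, 4]).all()


class TestSensitivityCompare:
    def test_identical_maps_zero_change(self, grid10, rng):
        ref = RasterLayer(grid10, rng.integers(1, 5, size=grid10.shape).astype(float))
        assert sensitivity_compare(ref, ref) == (0.0, 0.0, 0.0)

    def test_every_low_bumped_to_moderate(self, grid10, rng):
        ref_vals = rng.integers(1, 5, size=grid10.shape).astype(float)
        alt_vals = np.where(ref_vals == 1, 2, ref_vals)
        changed, inc, dec = sensitivity_compare(RasterLayer(grid10, ref_vals), RasterLayer(grid10, alt_vals))
        pct_low = (ref_vals == 1).mean() * 100.0
        assert changed == pytest.approx(pct_low)
        assert inc == pytest.approx(pct_low)
        assert dec == 0.0

    def test_partition_identity_on_random_pairs(self, grid10, rng):
        for _ in range(5):
            a = RasterLayer(grid10, rng.integers(1, 5, size=grid10.shape).astype(float))
            b = RasterLayer(grid10, rng.integers(1, 5, size=grid10.shape).astype(float))
            changed, inc, dec = sensitivity_compare(a, b)
            assert changed == pytest.approx(inc + dec, abs=1e-12)


class TestScenarioMonotonicity:
    def test_highest_geq_reference_geq_lowest_per_factor_and_index(self):
        cfg = SyntheticConfig(seed=11, grid=GridSpec(40, 40, 0.0, 200_000.0, 5000.0))
        f = gen_threat_factors(cfg)
        maps = {
            name: compute_threat_index(
                SCENARIOS[name], f["density"], f["cropland"], f["roads"], f["provinces"],
                f["tree_loss"], f["burn_trend"], f["temp_current"], f["temp_future"],
                f["precip_current"], f["precip_future"], f["urban"],
            )
            for name in ("highest", "reference", "lowest")
        }
        for factor in maps["reference"].layer_scores:
            hi = maps["highest"].layer_scores[factor].values
            ref = maps["reference"].layer_scores[factor].values
            lo = maps["lowest"].layer_scores[factor].values
            ok = np.isfinite(hi) & np.isfinite(ref) & np.isfinite(lo)
            assert np.all(hi[ok] >= ref[ok] - 1e-9), factor
            assert np.all(ref[ok] >= lo[ok] - 1e-9), factor
        ok = np.isfinite(maps["highest"].index.values)
        assert np.all(maps["highest"].index.values[ok] >= maps["lowest"].index.values[ok] - 1e-9)
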