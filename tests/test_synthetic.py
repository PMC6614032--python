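"""The synthetic generator: city sampling, model/reference fields, masks."""
import numpy as np
import pytest

import urbheat as uh
from urbheat.errors import ConfigError
from urbheat.synthetic import CMIP5_GRID_SHAPES, DEFAULT_STRATA


def _noiseless_truth(**kw):
    defaults = dict(model_biases={"m0": 0.0, "m1": 1.5}, noise_sd=0.0, seed=1)
    defaults.update(kw)
    return uh.SyntheticTruth(**defaults)


class TestCityTable:
    def test_requested_count_and_schema(self):
        df = uh.generate_city_table(246, seed=5)
        assert len(df) == 246
        assert df["city_id"].is_unique
        assert (df["population"] >= 15_000).all()
        assert df["lat"].between(-90, 90).all()
        assert (df["lon"] >= -180).all() and (df["lon"] < 180).all()

    def test_zero_cities(self):
        df = uh.generate_city_table(0, seed=5)
        assert len(df) == 0
        assert "ecoregion_domain" in df.columns

    def test_stratum_counts_track_proportions(self):
        n = 10_000
        df = uh.generate_city_table(n, seed=7)
        for axis, props in DEFAULT_STRATA.items():
            counts = df[axis].value_counts()
            for cat, p in props.items():
                se = np.sqrt(n * p * (1 - p))
                assert abs(counts.get(cat, 0) - n * p) <= 3 * se

    def test_latitude_consistent_with_ecoregion(self):
        df = uh.generate_city_table(500, seed=3)
        polar = df[df["ecoregion_domain"] == "polar"]["lat"].abs()
        tropical = df[df["ecoregion_domain"] == "humid tropical"]["lat"].abs()
        assert polar.min() >= 55.0
        assert tropical.max() <= 23.5

    def test_deterministic_given_seed(self):
        a = uh.generate_city_table(100, seed=11)
        b = uh.generate_city_table(100, seed=11)
        assert a.equals(b)

    def test_bad_proportions_rejected(self):
        with pytest.raises(ConfigError):
            uh.generate_city_table(10, {"gni_stratum": {"<1045": 0.9}}, seed=0)


class TestModelField:
    def test_pure_climatology_is_periodic(self):
        """With no warming, bias, or noise, each calendar month repeats."""
        truth = _noiseless_truth(
            scenarios={"flat": uh.Trajectory("ramp", 2200, 2300)},
            delta_2100={"flat": 1.0},
        )
        grid = uh.RegularGrid.global_grid(9, 18)
        fld = uh.simulate_model_field(grid, "flat", "m0", truth, years=(1901, 2100), seed=0)
        jan = fld.values[0::12]
        assert np.ptp(jan, axis=0).max() == 0.0

    def test_equatorial_change_matches_closed_form(self):
        """At an amp=1 cell with g saturated over the future window, the
        recovered period change equals delta * (1 - mean g over baseline)."""
        truth = _noiseless_truth(delta_2100={"low": 4.0, "high": 5.0})
        grid = uh.RegularGrid.global_grid(45, 90)  # has a center exactly at lat 0
        i_eq = int(np.argmin(np.abs(grid.lat_centers)))
        assert grid.lat_centers[i_eq] == 0.0
        fld = uh.simulate_model_field(grid, "low", "m0", truth, seed=0)
        t = fld.time
        base = fld.values[np.isin(t.years, range(1988, 2018)), i_eq, 0].mean()
        fut = fld.values[np.isin(t.years, range(2071, 2101)), i_eq, 0].mean()
        traj = truth.trajectory("low")
        assert traj.mean_g(2071, 2100) == 1.0  # saturated by 2045
        expected = 4.0 * (1.0 - traj.mean_g(1988, 2017))
        assert fut - base == pytest.approx(expected, abs=1e-9)
        assert fut - base == pytest.approx(truth.expected_change(0.0, "low"), abs=1e-9)

    def test_hemisphere_phase_opposition(self):
        truth = _noiseless_truth()
        grid = uh.RegularGrid.global_grid(12, 24)
        fld = uh.simulate_model_field(grid, "high", "m0", truth, years=(2000, 2000), seed=0)
        north = fld.values[:, -1, 0]  # northernmost row
        south = fld.values[:, 0, 0]
        assert int(np.argmax(north)) + 1 == 7  # July peak
        assert int(np.argmax(south)) + 1 == 1  # January peak

    def test_same_seed_bitwise_identical(self):
        truth = uh.default_truth(["m0"], noise_sd=0.7, seed=0)
        grid = uh.RegularGrid.global_grid(8, 16)
        a = uh.simulate_model_field(grid, "high", "m0", truth, years=(1990, 1999), seed=42)
        b = uh.simulate_model_field(grid, "high", "m0", truth, years=(1990, 1999), seed=42)
        assert np.array_equal(a.values, b.values)

    def test_unknown_scenario_or_model_rejected(self):
        truth = _noiseless_truth()
        grid = uh.RegularGrid.global_grid(4, 8)
        with pytest.raises(ConfigError):
            uh.simulate_model_field(grid, "rcp6", "m0", truth)
        with pytest.raises(ConfigError):
            uh.simulate_model_field(grid, "high", "nosuch", truth)

    def test_full_cmip5_resolution_range_supported(self):
        """Native grids spanning the ensemble's coarsest to finest members."""
        truth = _noiseless_truth()
        for name in ("CanESM2", "MRI-CGCM3", "CCSM4"):
            n_lat, n_lon = CMIP5_GRID_SHAPES[name]
            grid = uh.RegularGrid.global_grid(n_lat, n_lon)
            fld = uh.simulate_model_field(grid, "high", "m0", truth, years=(2000, 2001), seed=1)
            assert fld.values.shape == (24, n_lat, n_lon)


class TestReferenceField:
    def test_reference_is_unbiased_model(self):
        """Noiseless reference equals a model field minus that model's bias
        wherever the historical trajectories coincide."""
        truth = _noiseless_truth()
        grid = uh.RegularGrid.global_grid(9, 18)
        ref = uh.simulate_reference_field(grid, truth, years=(1961, 1990), seed=0)
        mod = uh.simulate_model_field(grid, "high", "m1", truth, years=(1961, 1990), seed=0)
        np.testing.assert_allclose(ref.values, mod.values - 1.5, atol=1e-12)

    def test_ocean_cells_missing_land_finite(self):
        truth = _noiseless_truth()
        grid = uh.RegularGrid.global_grid(9, 18)
        mask = uh.make_land_mask(grid, "latband-continents")
        ref = uh.simulate_reference_field(grid, truth, years=(1961, 1990), mask=mask, seed=0)
        assert np.isfinite(ref.values[:, mask.is_land]).all()
        assert np.isnan(ref.values[:, ~mask.is_land]).all()

    def test_calibration_window_january_mean_closed_form(self):
        truth = _noiseless_truth()
        grid = uh.RegularGrid.global_grid(36, 72)
        ref = uh.simulate_reference_field(grid, truth, years=(1961, 1990), seed=0)
        jan = ref.values[0::12].mean(axis=0)
        lats = grid.lat_centers
        # g == 0 through 1990, so only the stationary seasonal part remains
        expected = truth.climatology(lats, 1)
        np.testing.assert_allclose(jan, np.broadcast_to(expected[:, None], jan.shape), atol=1e-9)


class TestLandMask:
    def test_all_land(self):
        grid = uh.RegularGrid.global_grid(6, 12)
        assert uh.make_land_mask(grid, "all-land").is_land.all()

    def test_blob_fraction_honored(self):
        grid = uh.RegularGrid.global_grid(90, 180)
        mask = uh.make_land_mask(grid, "random-blobs", seed=1, land_fraction=0.3)
        assert 0.25 <= mask.land_fraction <= 0.35

    def test_deterministic_given_seed(self):
        grid = uh.RegularGrid.global_grid(30, 60)
        a = uh.make_land_mask(grid, "random-blobs", seed=9)
        b = uh.make_land_mask(grid, "random-blobs", seed=9)
        assert np.array_equal(a.is_land, b.is_land)


def test_truth_yaml_round_trip(tmp_path):
    import yaml

    truth = uh.default_truth(["a", "b"], noise_sd=0.25, seed=3)
    path = tmp_path / "truth.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(truth.to_dict(), fh)
    with open(path) as fh:
        back = uh.SyntheticTruth.from_dict(yaml.safe_load(fh))
    assert back == truth


def test_truth_validation():
    with pytest.raises(ConfigError):
        uh.SyntheticTruth(delta_2100={"low": 5.0, "high": 1.0})  # high must exceed low
    with pytest.raises(ConfigError):
        uh.SyntheticTruth(
            scenarios={"low": uh.Trajectory("ramp", 1950, 2000),
                       "high": uh.Trajectory("accel", 1990, 2100)}
        )  # warming before 1990
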