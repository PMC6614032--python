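"""Period climatologies, ensemble means, and change computation."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import urbheat as uh
from urbheat.climatology import climatology_from_monthly, ensemble_of_extremes
from urbheat.errors import InputError


def _series(values, years=(1988, 2017), city="c", scenario="s", model="m"):
    t = uh.MonthTime.from_years(*years)
    return uh.CitySeries(city, model, scenario, t, np.asarray(values, dtype=float),
                         (0, 0), False)


def _clim(monthly, city="c", scenario="s", period="2100", n_models=1):
    return climatology_from_monthly(
        np.asarray(monthly, dtype=float), city, scenario, period, (2071, 2100),
        n_models=n_models,
    )


class TestPeriodClimatology:
    def test_constant_series(self):
        s = _series(np.full(360, 20.0))
        c = uh.period_climatology(s, (1988, 2017), label="2017")
        assert np.all(c.monthly_means == 20.0)
        assert c.annual_mean == 20.0
        assert (c.hottest_month, c.hottest_value) == (1, 20.0)  # tie -> month 1
        assert (c.coldest_month, c.coldest_value) == (1, 20.0)

    def test_arithmetic_on_known_monthly_values(self):
        vals = np.tile(np.arange(12.0), 30)  # every year: 0..11
        c = uh.period_climatology(_series(vals), (1988, 2017))
        np.testing.assert_array_equal(c.monthly_means, np.arange(12.0))
        assert c.annual_mean == 5.5
        assert (c.hottest_month, c.hottest_value) == (12, 11.0)
        assert (c.coldest_month, c.coldest_value) == (1, 0.0)

    def test_noiseless_northern_city_peaks_in_july(self):
        truth = uh.SyntheticTruth(model_biases={"m": 0.0}, noise_sd=0.0)
        grid = uh.RegularGrid.global_grid(18, 36)
        fld = uh.simulate_model_field(grid, "high", "m", truth, years=(1988, 2017), seed=0)
        i, j = uh.cell_of(grid, 48.0, 2.0)
        s = _series(fld.values[:, i, j])
        c = uh.period_climatology(s, (1988, 2017))
        assert c.hottest_month == truth.phase_north == 7
        assert c.coldest_month == 1

    def test_incomplete_coverage_rejected(self):
        s = _series(np.zeros(120), years=(2000, 2009))
        with pytest.raises(InputError):
            uh.period_climatology(s, (1995, 2004))

    @given(shift=st.floats(-30, 30))
    @settings(max_examples=50, deadline=None)
    def test_shift_equivariance(self, shift):
        rng = np.random.default_rng(17)
        vals = rng.normal(10, 8, size=360)
        c0 = uh.period_climatology(_series(vals), (1988, 2017))
        c1 = uh.period_climatology(_series(vals + shift), (1988, 2017))
        assert c1.annual_mean == pytest.approx(c0.annual_mean + shift, abs=1e-9)
        assert c1.hottest_value == pytest.approx(c0.hottest_value + shift, abs=1e-9)
        assert c1.coldest_value == pytest.approx(c0.coldest_value + shift, abs=1e-9)
        assert c1.hottest_month == c0.hottest_month
        assert (c1.hottest_value - c1.coldest_value) == pytest.approx(
            c0.hottest_value - c0.coldest_value, abs=1e-9
        )


class TestEnsemble:
    def test_identical_models_unchanged(self):
        c = _clim(np.arange(12.0))
        e = uh.ensemble_climatology([c, c, c])
        np.testing.assert_array_equal(e.monthly_means, c.monthly_means)
        assert e.n_models == 3

    def test_constant_offset_models_average_to_midpoint(self):
        a = _clim(np.arange(12.0))
        b = _clim(np.arange(12.0) + 2.0)
        e = uh.ensemble_climatology([a, b])
        np.testing.assert_allclose(e.monthly_means, np.arange(12.0) + 1.0)

    def test_mixed_keys_rejected(self):
        with pytest.raises(InputError):
            uh.ensemble_climatology([_clim(np.zeros(12)), _clim(np.zeros(12), city="other")])

    def test_extremes_first_ordering_averages_per_model_extremes(self):
        """Models peaking in different months: averaging the extreme values
        differs from the extreme of the averaged curve."""
        a = np.zeros(12); a[6] = 10.0  # July peak
        b = np.zeros(12); b[7] = 10.0  # August peak
        ens = uh.ensemble_climatology([_clim(a), _clim(b)])
        ext = ensemble_of_extremes([_clim(a), _clim(b)])
        assert ens.hottest_value == 5.0
        assert ext.hottest_value == 10.0
        np.testing.assert_array_equal(ens.monthly_means, ext.monthly_means)


class TestComputeChange:
    def test_equal_periods_zero_change(self):
        base = _clim(np.arange(12.0), period="2017")
        fut = _clim(np.arange(12.0), period="2100")
        ch = uh.compute_change(base, fut)
        assert ch.d_annual == ch.d_hottest == ch.d_coldest == 0.0
        assert ch.seasonal_range_baseline == 11.0

    def test_uniform_shift(self):
        base = _clim(np.arange(12.0), period="2017")
        fut = _clim(np.arange(12.0) + 3.0, period="2100")
        ch = uh.compute_change(base, fut)
        assert ch.d_annual == pytest.approx(3.0)
        assert ch.d_hottest == pytest.approx(3.0)
        assert ch.d_coldest == pytest.approx(3.0)
        assert ch.abs_hottest_future == pytest.approx(14.0)

    def test_hottest_month_may_shift_between_periods(self):
        """July 25 degC baseline; future +2 everywhere except August +4,
        so August (29) overtakes July (27): d_hottest = 29 - 25 = 4."""
        base_m = np.full(12, 15.0)
        base_m[6] = 25.0
        fut_m = base_m + 2.0  # July now 27
        fut_m[7] = 29.0  # August overtakes as the new hottest month
        base = _clim(base_m, period="2017")
        fut = _clim(fut_m, period="2100")
        ch = uh.compute_change(base, fut)
        assert fut.hottest_month == 8
        assert ch.d_hottest == pytest.approx(4.0)
        # fixing the baseline's month instead reads July: 27 - 25 = 2
        ch_fixed = uh.compute_change(base, fut, fixed_baseline_month=True)
        assert ch_fixed.d_hottest == pytest.approx(2.0)

    def test_mismatched_city_rejected(self):
        with pytest.raises(InputError):
            uh.compute_change(_clim(np.zeros(12)), _clim(np.zeros(12), city="other"))

    def test_per_period_extreme_bounded_below_by_baseline_month_change(self, rng):
        for _ in range(20):
            base = _clim(rng.normal(10, 6, 12), period="2017")
            fut = _clim(rng.normal(12, 6, 12), period="2100")
            ch = uh.compute_change(base, fut)
            at_base_month = (
                fut.monthly_means[base.hottest_month - 1] - base.hottest_value
            )
            assert ch.d_hottest >= at_base_month - 1e-12


class TestEnsembleChangeCommutation:
    def test_annual_change_commutes_with_ensembling(self, rng):
        """ensemble-then-change == mean of per-model changes (linearity)."""
        bases, futs = [], []
        for _ in range(5):
            bases.append(_clim(rng.normal(10, 5, 12), period="2017"))
            futs.append(_clim(rng.normal(13, 5, 12), period="2100"))
        ens_change = uh.compute_change(
            uh.ensemble_climatology(bases), uh.ensemble_climatology(futs)
        )
        per_model = [uh.compute_change(b, f) for b, f in zip(bases, futs)]
        assert ens_change.d_annual == pytest.approx(
            np.mean([c.d_annual for c in per_model]), abs=1e-9
        )

    def test_hottest_change_orderings_agree_without_noise(self, noiseless_run):
        """In the noiseless synthetic study all models share the seasonal
        shape, so both ensemble orderings give the same hottest-month change."""
        cfg = noiseless_run.config
        alt = uh.run_pipeline(
            uh.default_config(seed=cfg.seed, noise_sd=0.0, ensemble_ordering="extremes_first")
        )
        a = noiseless_run.changes.set_index(["city_id", "scenario", "period"])["d_hottest"]
        b = alt.changes.set_index(["city_id", "scenario", "period"])["d_hottest"]
        np.testing.assert_allclose(a.values, b.reindex(a.index).values, atol=1e-9)
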