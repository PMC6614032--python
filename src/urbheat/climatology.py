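"""30-year period climatologies, ensemble means, and temperature changes.

A period climatology holds the 12 calendar-month means of monthly mean
temperature over a 30-year window, the annual mean (mean of the 12
monthly values), and the hottest/coldest months.  The ensemble mean is
formed on the monthly climatologies across models first, and extremes
are then re-derived from the ensemble curve — averaging extremes picked
in different months across models would mix seasons.  Changes are future
minus baseline; by default the hottest/coldest months are identified
independently in each period (the hottest month may shift), with a flag
to pin them at the baseline's months instead.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import InputError
from .extract import CitySeries
from .grid import month_window_indices


@dataclass
class PeriodClimatology:
    """Monthly 30-year means plus derived annual/extreme summaries."""

    city_id: str
    scenario: str
    period: str  # label, e.g. "2017"
    window: Tuple[int, int]
    monthly_means: np.ndarray  # (12,), degC
    annual_mean: float
    hottest_month: int  # 1..12, lowest index on ties
    hottest_value: float
    coldest_month: int
    coldest_value: float
    n_models: int = 1
    model_id: Optional[str] = None


def _derive(monthly: np.ndarray):
    monthly = np.asarray(monthly, dtype=float)
    if monthly.shape != (12,):
        raise InputError("monthly means must have 12 entries")
    hot = int(np.argmax(monthly))  # first max -> lowest month index on ties
    cold = int(np.argmin(monthly))
    return (
        float(monthly.mean()),
        hot + 1,
        float(monthly[hot]),
        cold + 1,
        float(monthly[cold]),
    )


def climatology_from_monthly(
    monthly: np.ndarray,
    city_id: str,
    scenario: str,
    period: str,
    window: Tuple[int, int],
    n_models: int = 1,
    model_id: Optional[str] = None,
) -> PeriodClimatology:
    annual, hm, hv, cm, cv = _derive(monthly)
    return PeriodClimatology(
        city_id, scenario, period, window, np.asarray(monthly, dtype=float),
        annual, hm, hv, cm, cv, n_models, model_id,
    )


def period_climatology(
    series: CitySeries, period: Tuple[int, int], label: Optional[str] = None
) -> PeriodClimatology:
    """Reduce a city series to its climatology over [first_year, last_year]."""
    idx = month_window_indices(series.time, *period)
    months = series.time.months[idx]
    sub = np.asarray(series.values, dtype=float)[idx]
    monthly = np.array([sub[months == m].mean() for m in range(1, 13)])
    return climatology_from_monthly(
        monthly,
        series.city_id,
        series.scenario,
        label if label is not None else str(period[1]),
        period,
        n_models=1,
        model_id=series.model_id,
    )


def ensemble_climatology(per_model: Sequence[PeriodClimatology]) -> PeriodClimatology:
    """Unweighted model mean of the monthly climatologies; extremes re-derived."""
    if not per_model:
        raise InputError("ensemble of zero models")
    first = per_model[0]
    for c in per_model[1:]:
        if (c.city_id, c.scenario, c.period) != (first.city_id, first.scenario, first.period):
            raise InputError("ensemble inputs mix city/scenario/period")
    monthly = np.mean([c.monthly_means for c in per_model], axis=0)
    return climatology_from_monthly(
        monthly,
        first.city_id,
        first.scenario,
        first.period,
        first.window,
        n_models=sum(c.n_models for c in per_model),
        model_id=None,
    )


def ensemble_of_extremes(per_model: Sequence[PeriodClimatology]) -> PeriodClimatology:
    """Alternative ordering: identify extremes per model, then average them.

    The monthly curve is still the model mean; hottest/coldest values are
    means of the per-model extreme values (months may differ across
    models; the reported month is the ensemble curve's extreme month).
    """
    ens = ensemble_climatology(per_model)
    return replace(
        ens,
        hottest_value=float(np.mean([c.hottest_value for c in per_model])),
        coldest_value=float(np.mean([c.coldest_value for c in per_model])),
    )


@dataclass
class ChangeRecord:
    """Ensemble-mean changes for one city, scenario, and future period."""

    city_id: str
    scenario: str
    period: str  # future period label
    d_annual: float
    d_hottest: float
    d_coldest: float
    abs_hottest_future: float
    seasonal_range_baseline: float
    n_models: int = 1


def compute_change(
    baseline: PeriodClimatology,
    future: PeriodClimatology,
    fixed_baseline_month: bool = False,
) -> ChangeRecord:
    """Future-minus-baseline changes in annual/hottest/coldest-month means.

    With ``fixed_baseline_month=True`` the future hottest (coldest) value
    is read at the baseline's hottest (coldest) month instead of the
    future period's own extreme month.
    """
    if (baseline.city_id, baseline.scenario) != (future.city_id, future.scenario):
        raise InputError("baseline and future must share city and scenario")
    if fixed_baseline_month:
        fut_hot = float(future.monthly_means[baseline.hottest_month - 1])
        fut_cold = float(future.monthly_means[baseline.coldest_month - 1])
    else:
        fut_hot = future.hottest_value
        fut_cold = future.coldest_value
    return ChangeRecord(
        city_id=baseline.city_id,
        scenario=baseline.scenario,
        period=future.period,
        d_annual=future.annual_mean - baseline.annual_mean,
        d_hottest=fut_hot - baseline.hottest_value,
        d_coldest=fut_cold - baseline.coldest_value,
        abs_hottest_future=future.hottest_value,
        seasonal_range_baseline=baseline.hottest_value - baseline.coldest_value,
        n_models=future.n_models,
    )
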