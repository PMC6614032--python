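"""Result surfaces: stratified change tables, exceedance reports, scatter exports.

Stratum means are unweighted averages over cities (no population
weighting).  Cities lacking a stratum attribute are excluded from that
analysis only, and the exclusion is logged — never silently global.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .strata import ECOREGION_DOMAINS, WHO_REGIONS

log = logging.getLogger(__name__)

CHANGE_QUANTITIES = ("d_annual", "d_coldest", "d_hottest")


def _check_join(changes: pd.DataFrame, cities: pd.DataFrame) -> pd.DataFrame:
    orphans = set(changes["city_id"]) - set(cities["city_id"])
    if orphans:
        raise DataError(f"change records with no city record: {sorted(orphans)[:5]}")
    return changes.merge(cities, on="city_id", how="left", validate="many_to_one")


def stratified_table(changes: pd.DataFrame, cities: pd.DataFrame) -> pd.DataFrame:
    """Mean changes by (WHO region, ecoregion domain) stratum.

    One row per stratum (all region x domain combinations, empty ones with
    count 0 and missing means); columns ``n_cities`` plus
    ``{scenario}_{period}_{quantity}`` for each scenario/future-period pair.
    """
    merged = _check_join(changes, cities)
    incomplete = merged[["who_region", "ecoregion_domain"]].isna().any(axis=1)
    if incomplete.any():
        n_dropped = merged.loc[incomplete, "city_id"].nunique()
        log.info("stratified_table: excluded %d cities lacking stratum attributes", n_dropped)
        merged = merged[~incomplete]

    combos = [
        (sc, per)
        for sc in sorted(merged["scenario"].unique())
        for per in sorted(merged["period"].astype(str).unique())
    ]
    index = pd.MultiIndex.from_product(
        [WHO_REGIONS, ECOREGION_DOMAINS], names=["who_region", "ecoregion_domain"]
    )
    out = pd.DataFrame(index=index)
    counts = merged.groupby(["who_region", "ecoregion_domain"])["city_id"].nunique()
    out["n_cities"] = counts.reindex(index).fillna(0).astype(int)
    for sc, per in combos:
        sub = merged[(merged["scenario"] == sc) & (merged["period"].astype(str) == per)]
        means = sub.groupby(["who_region", "ecoregion_domain"])[list(CHANGE_QUANTITIES)].mean()
        for q in CHANGE_QUANTITIES:
            col = f"{sc}_{per}_{q}"
            out[col] = means[q].reindex(index) if not means.empty else np.nan
    return out.reset_index()


@dataclass
class ExceedanceReport:
    """Cities whose change (or level) passes a temperature cutoff."""

    quantity: str
    cutoff: float
    comparison: str  # ">" or ">="
    frame: pd.DataFrame  # columns: scenario, period, count, cities (";"-joined)

    def cities(self, scenario: str, period: str) -> List[str]:
        row = self.frame[
            (self.frame["scenario"] == scenario)
            & (self.frame["period"].astype(str) == str(period))
        ]
        if row.empty:
            return []
        joined = row["cities"].iloc[0]
        return joined.split(";") if joined else []


def exceedance_report(
    changes: pd.DataFrame,
    cities: pd.DataFrame,
    quantity: str,
    cutoff: float,
    comparison: str = ">",
) -> ExceedanceReport:
    """Per scenario/period, the alphabetical list of qualifying cities."""
    if quantity not in changes.columns:
        raise ConfigError(f"unknown quantity {quantity!r}")
    if comparison not in (">", ">="):
        raise ConfigError(f"comparison must be '>' or '>=', got {comparison!r}")
    merged = _check_join(changes, cities)
    hit = (
        merged[quantity] > cutoff if comparison == ">" else merged[quantity] >= cutoff
    )
    rows = []
    for (sc, per), sub in merged.groupby(["scenario", "period"], sort=True):
        names = sorted(sub.loc[hit.loc[sub.index], "name"].astype(str))
        rows.append(
            {"scenario": sc, "period": str(per), "count": len(names), "cities": ";".join(names)}
        )
    return ExceedanceReport(quantity, cutoff, comparison, pd.DataFrame(rows))


_SCATTER_AXES = {
    "latitude": ("lat", lambda s: s.astype(float)),
    "seasonal_range": ("seasonal_range_baseline", lambda s: s.astype(float)),
    "log10_population": ("population", lambda s: np.log10(s.astype(float))),
}


def scatter_export(
    changes: pd.DataFrame,
    cities: pd.DataFrame,
    x_axis: str,
    period: str,
    scenario: str,
) -> pd.DataFrame:
    """Per-city (x, hottest-month change) table behind the scatter figures.

    Cities with a missing x attribute are excluded from this export only.
    """
    if x_axis not in _SCATTER_AXES:
        raise ConfigError(f"unknown x_axis {x_axis!r}")
    src_col, transform = _SCATTER_AXES[x_axis]
    sub = changes[
        (changes["scenario"] == scenario) & (changes["period"].astype(str) == str(period))
    ]
    merged = _check_join(sub, cities)
    ok = merged[src_col].notna()
    if (~ok).any():
        log.info("scatter_export[%s]: excluded %d cities missing %s", x_axis, int((~ok).sum()), src_col)
        merged = merged[ok]
    out = pd.DataFrame(
        {
            "city_id": merged["city_id"].values,
            "name": merged["name"].values,
            "x": transform(merged[src_col]).values,
            "d_hottest": merged["d_hottest"].values,
            "ecoregion_domain": merged["ecoregion_domain"].values,
        }
    )
    return out.sort_values("city_id", kind="stable").reset_index(drop=True)
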