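"""Mapping cities to grid cells and pulling their monthly series.

A city is assigned the grid cell containing its coordinates.  When that
cell is not land (coastal or ocean per the mask), the land cell whose
center is nearest by great-circle (haversine) distance is used instead
— index-space distance would be wrong near the poles where meridians
converge.  Exact distance ties break deterministically to the lowest
latitude index, then lowest longitude index.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .errors import ConfigError, DataError, InputError
from .grid import LandMask, MonthTime, MonthlyField, cell_of, haversine_km


@dataclass
class CitySeries:
    """One city's monthly temperature series from one model/scenario."""

    city_id: str
    model_id: str
    scenario: str
    time: MonthTime
    values: np.ndarray
    source_cell: Tuple[int, int]
    relocated: bool


def locate_city_cell(city, grid, mask: LandMask) -> Tuple[Tuple[int, int], bool]:
    """Grid cell serving a city: its own cell if land, else nearest land cell.

    ``city`` needs ``lat`` and ``lon`` attributes (a CityRecord row).
    Returns ((lat_index, lon_index), relocated).
    """
    if mask.grid != grid:
        raise InputError("mask is on a different grid")
    if not mask.is_land.any():
        raise ConfigError("land mask has no land cells")
    i, j = cell_of(grid, float(city.lat), float(city.lon))
    if mask.is_land[i, j]:
        return (i, j), False
    li, lj = np.nonzero(mask.is_land)  # row-major: lat index, then lon index
    d = haversine_km(
        float(city.lat), float(city.lon), grid.lat_centers[li], grid.lon_centers[lj]
    )
    # argmin returns the first minimum; (li, lj) is already in lexicographic
    # order, which is exactly the documented tie-break
    k = int(np.argmin(d))
    return (int(li[k]), int(lj[k])), True


def extract_city_series(
    field: MonthlyField,
    cities,
    mask: LandMask,
    model_id: str = "",
    scenario: str = "",
) -> List[CitySeries]:
    """One monthly series per city row, copied unmodified from its cell."""
    out: List[CitySeries] = []
    for city in cities.itertuples(index=False):
        (i, j), relocated = locate_city_cell(city, field.grid, mask)
        vals = field.values[:, i, j]
        if not np.isfinite(vals).all():
            raise DataError(
                f"city {city.city_id}: located cell ({i}, {j}) is missing in the field"
            )
        out.append(
            CitySeries(
                city_id=str(city.city_id),
                model_id=model_id,
                scenario=scenario,
                time=field.time,
                values=vals.copy(),
                source_cell=(i, j),
                relocated=relocated,
            )
        )
    return out
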