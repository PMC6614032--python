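"""Grid geometry, monthly time axis, and gridded-field containers.

All fields in the pipeline live on regular latitude-longitude grids with
cell-center registration: a cell is the half-open box
``[edge, edge + step)`` in both axes and carries its value at the center
``edge + step/2``.  The "standard grid" is the global 0.5-degree grid
(360 x 720) with centers at latitudes -89.75 ... 89.75 and longitudes
-179.75 ... 179.75, matching CRU-TS registration.

Longitudes are stored in [-180, 180); inputs on [0, 360) are normalized
on read.  The monthly time axis is a gap-free sequence with a uniform
12-month calendar.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .errors import InputError, OutOfDomainError

EARTH_RADIUS_KM = 6371.0088


def normalize_lon(lon):
    """Map longitudes onto [-180, 180)."""
    return ((np.asarray(lon, dtype=float) + 180.0) % 360.0) - 180.0


@dataclass(frozen=True)
class RegularGrid:
    """A regular lat-lon grid of half-open cells with center registration."""

    lat_edge_south: float
    lon_edge_west: float
    lat_step: float
    lon_step: float
    n_lat: int
    n_lon: int

    def __post_init__(self):
        if self.lat_step <= 0 or self.lon_step <= 0:
            raise InputError("grid steps must be positive")
        if self.n_lat * self.lat_step > 180.0 + 1e-9:
            raise InputError("latitude span exceeds 180 degrees")
        if self.n_lon * self.lon_step > 360.0 + 1e-9:
            raise InputError("longitude span exceeds 360 degrees")

    # -- geometry ---------------------------------------------------------
    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_edge_south + self.lat_step * (np.arange(self.n_lat) + 0.5)

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_edge_west + self.lon_step * (np.arange(self.n_lon) + 0.5)

    @property
    def lat_span(self) -> Tuple[float, float]:
        return (self.lat_edge_south, self.lat_edge_south + self.n_lat * self.lat_step)

    @property
    def is_global_lon(self) -> bool:
        return abs(self.n_lon * self.lon_step - 360.0) < 1e-9

    def center(self, lat_index: int, lon_index: int) -> Tuple[float, float]:
        return (
            self.lat_edge_south + self.lat_step * (lat_index + 0.5),
            self.lon_edge_west + self.lon_step * (lon_index + 0.5),
        )

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.n_lat, self.n_lon)

    # -- constructors -----------------------------------------------------
    @classmethod
    def standard(cls) -> "RegularGrid":
        """The global 0.5-degree grid used as the common analysis grid."""
        return cls(-90.0, -180.0, 0.5, 0.5, 360, 720)

    @classmethod
    def global_grid(cls, n_lat: int, n_lon: int) -> "RegularGrid":
        """A global grid with the given cell counts (e.g. a GCM's native grid)."""
        return cls(-90.0, -180.0, 180.0 / n_lat, 360.0 / n_lon, n_lat, n_lon)


def cell_of(grid: RegularGrid, lat: float, lon: float) -> Tuple[int, int]:
    """Return the (lat_index, lon_index) of the cell containing a point.

    Cells are half-open ``[edge, edge+step)``; a point on a shared edge
    belongs to the higher-index cell.  Longitude wraps modulo 360.
    Raises :class:`OutOfDomainError` if the latitude falls outside the
    grid's (half-open) latitude span.
    """
    lo, hi = grid.lat_span
    if not (lo <= lat < hi):
        raise OutOfDomainError(
            f"latitude {lat} outside grid span [{lo}, {hi})"
        )
    i = int(np.floor((lat - grid.lat_edge_south) / grid.lat_step))
    # the division rounds at sub-ulp offsets from a shared edge; correct
    # against the exact half-open interval [edge + i*step, edge + (i+1)*step)
    if lat < grid.lat_edge_south + i * grid.lat_step:
        i -= 1
    elif lat >= grid.lat_edge_south + (i + 1) * grid.lat_step:
        i += 1
    i = min(max(i, 0), grid.n_lat - 1)

    lon_n = float(normalize_lon(lon))
    rel = (lon_n - grid.lon_edge_west) % 360.0
    j = int(np.floor(rel / grid.lon_step))
    if j >= grid.n_lon:
        if grid.is_global_lon:
            j = j % grid.n_lon
        else:
            raise OutOfDomainError(
                f"longitude {lon} outside grid span starting {grid.lon_edge_west}"
            )

    def _in_cell(jj: int) -> bool:
        west = grid.lon_edge_west + jj * grid.lon_step
        return (lon_n - west) % 360.0 < grid.lon_step

    if not _in_cell(j):
        for jj in ((j + 1) % grid.n_lon, (j - 1) % grid.n_lon):
            if _in_cell(jj):
                j = jj
                break
    return i, j


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between points in degrees (broadcasting)."""
    p1, l1, p2, l2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    a = np.sin((p2 - p1) / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass(frozen=True)
class MonthTime:
    """A gap-free monthly time axis with a uniform 12-month calendar."""

    start_year: int
    start_month: int
    n_months: int

    def __post_init__(self):
        if not (1 <= self.start_month <= 12):
            raise InputError("start_month must be 1..12")
        if self.n_months < 0:
            raise InputError("n_months must be non-negative")

    def index_of(self, year: int, month: int) -> int:
        idx = (year - self.start_year) * 12 + (month - self.start_month)
        if not (0 <= idx < self.n_months):
            raise InputError(f"({year}, {month}) outside the time axis")
        return idx

    def year_month(self, index: int) -> Tuple[int, int]:
        if not (0 <= index < self.n_months):
            raise InputError(f"index {index} outside the time axis")
        q, r = divmod(self.start_month - 1 + index, 12)
        return self.start_year + q, r + 1

    @property
    def years(self) -> np.ndarray:
        """Calendar year of each time step."""
        return self.start_year + (self.start_month - 1 + np.arange(self.n_months)) // 12

    @property
    def months(self) -> np.ndarray:
        """Calendar month (1..12) of each time step."""
        return (self.start_month - 1 + np.arange(self.n_months)) % 12 + 1

    def covers(self, first_year: int, last_year: int) -> bool:
        try:
            self.index_of(first_year, 1)
            self.index_of(last_year, 12)
        except InputError:
            return False
        return True

    @classmethod
    def from_years(cls, first_year: int, last_year: int) -> "MonthTime":
        return cls(first_year, 1, 12 * (last_year - first_year + 1))


def month_window_indices(time: MonthTime, first_year: int, last_year: int) -> np.ndarray:
    """Indices of every month with first_year <= year <= last_year.

    The window must be fully covered by the series; the result has
    ``12 * (last_year - first_year + 1)`` entries with each calendar month
    contributing equally.
    """
    if first_year > last_year:
        raise InputError("window start after end")
    if not time.covers(first_year, last_year):
        raise InputError(
            f"window {first_year}-{last_year} not covered by series "
            f"starting {time.start_year}-{time.start_month:02d}"
        )
    first = time.index_of(first_year, 1)
    last = time.index_of(last_year, 12)
    return np.arange(first, last + 1)


@dataclass
class MonthlyField:
    """A gridded monthly temperature series in degrees Celsius.

    ``values`` has shape (n_months, n_lat, n_lon).  ``missing_mask`` is a
    per-cell boolean map (True = no data, e.g. ocean in observational
    products); values are NaN exactly where masked and finite elsewhere.
    """

    grid: RegularGrid
    time: MonthTime
    values: np.ndarray
    missing_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.time.n_months, self.grid.n_lat, self.grid.n_lon)
        if self.values.shape != expected:
            raise InputError(f"values shape {self.values.shape} != {expected}")
        if self.missing_mask is not None:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.grid.shape:
                raise InputError("missing_mask shape does not match grid")
        self.validate()

    def validate(self):
        if self.missing_mask is None:
            if not np.isfinite(self.values).all():
                raise InputError("non-finite values in a field with no missing mask")
        else:
            ok = np.isfinite(self.values[:, ~self.missing_mask]).all()
            if not ok:
                raise InputError("non-finite values at non-missing cells")

    @property
    def has_missing(self) -> bool:
        return self.missing_mask is not None and bool(self.missing_mask.any())

    def copy(self) -> "MonthlyField":
        return MonthlyField(
            self.grid,
            self.time,
            self.values.copy(),
            None if self.missing_mask is None else self.missing_mask.copy(),
        )


@dataclass
class LandMask:
    """Boolean land map on a grid; governs nearest-land city relocation."""

    grid: RegularGrid
    is_land: np.ndarray

    def __post_init__(self):
        self.is_land = np.asarray(self.is_land, dtype=bool)
        if self.is_land.shape != self.grid.shape:
            raise InputError("mask shape does not match grid")
        if not self.is_land.any():
            raise InputError("land mask has no land cells")

    @property
    def land_fraction(self) -> float:
        return float(self.is_land.mean())
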