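"""Delta-method bias adjustment against a reference climatology.

For each model, grid cell, and calendar month, the offset is the
observed-minus-simulated mean over a calibration window (1961-1990 by
default).  The offset is then added to the *entire* simulated series,
1901-2100, which operationalizes the stationarity assumption: a model's
bias is taken to be constant in time, so it cancels exactly from any
within-series difference — in particular from all downstream temperature
changes.

Cells missing in the reference (ocean, typically) carry missing offsets
and propagate missing into the adjusted field; silently mixing adjusted
and unadjusted data would corrupt comparisons.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .errors import InputError
from .grid import MonthlyField, RegularGrid, month_window_indices


def monthly_climatology(field: MonthlyField, window: Tuple[int, int]) -> np.ndarray:
    """Per-calendar-month means over a year window; shape (12, n_lat, n_lon).

    NaN (missing) cells stay NaN.
    """
    idx = month_window_indices(field.time, *window)
    months = field.time.months[idx]
    sub = field.values[idx]
    return np.stack([sub[months == m].mean(axis=0) for m in range(1, 13)])


@dataclass
class BiasOffsets:
    """12 additive per-calendar-month corrections per cell for one model."""

    grid: RegularGrid
    model_id: str
    offsets: np.ndarray  # (12, n_lat, n_lon), degC; NaN where reference missing
    calibration_window: Tuple[int, int]

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.offsets.shape != (12,) + self.grid.shape:
            raise InputError("offsets must have shape (12, n_lat, n_lon)")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.offsets).any(axis=0)


def compute_offsets(
    sim: MonthlyField,
    ref: MonthlyField,
    window: Tuple[int, int] = (1961, 1990),
    model_id: str = "",
) -> BiasOffsets:
    """offset[m, cell] = reference window mean - simulated window mean."""
    if sim.grid != ref.grid:
        raise InputError("simulated and reference fields are on different grids")
    off = monthly_climatology(ref, window) - monthly_climatology(sim, window)
    return BiasOffsets(sim.grid, model_id, off, window)


def apply_offsets(
    sim: MonthlyField, offsets: BiasOffsets, inplace: bool = False
) -> MonthlyField:
    """Add the calendar-month offsets to every month of the series.

    With ``inplace=True`` the input array is adjusted in place (the input
    field object must then no longer be used).
    """
    if sim.grid != offsets.grid:
        raise InputError("offsets were computed on a different grid")
    values = sim.values if inplace else sim.values.copy()
    # month m occupies a strided slice of the gap-free axis, so the add is
    # in place with no gather temporaries
    for m in range(1, 13):
        first = (m - sim.time.start_month) % 12
        values[first::12] += offsets.offsets[m - 1]
    missing = offsets.missing_mask
    if missing.any():
        values[:, missing] = np.nan
        out_missing = missing
    else:
        out_missing = None
    return MonthlyField(sim.grid, sim.time, values, out_missing)
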