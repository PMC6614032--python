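"""Interpolation of native-resolution model fields onto a target grid.

Bilinear interpolation among the 4 surrounding source cell centers, with
periodic longitude wraparound.  Target centers poleward of the outermost
source-center latitude are clamped to the nearest source latitude row
(no extrapolation beyond data support).  Values are treated as point
samples at cell centers, so interpolation reproduces constants exactly
and affine-in-(lat, lon) fields exactly away from the seam and clamp.
"""
from __future__ import annotations

from typing import Tuple

import numpy as np

from .errors import InputError
from .grid import MonthlyField, RegularGrid

_CHUNK_VALUES = 20_000_000  # cap temporaries to ~160 MB per gathered term


def _lat_weights(source: RegularGrid, target_lats: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """(lower row index j0, fractional weight toward row j0+1) per target lat."""
    c0 = source.lat_centers[0]
    p = (target_lats - c0) / source.lat_step
    p = np.clip(p, 0.0, source.n_lat - 1.0)  # polar clamp
    j0 = np.minimum(np.floor(p).astype(int), source.n_lat - 2)
    if source.n_lat == 1:
        return np.zeros_like(p, dtype=int), np.zeros_like(p)
    f = np.clip(p - j0, 0.0, 1.0)
    return j0, f


def _lon_weights(source: RegularGrid, target_lons: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(west index i0, east index i1, weight toward i1) with wraparound."""
    if not source.is_global_lon:
        raise InputError("bilinear regrid requires a longitudinally global source grid")
    c0 = source.lon_centers[0]
    d = (target_lons - c0) % 360.0
    k = np.floor(d / source.lon_step).astype(int)
    f = d / source.lon_step - k
    i0 = k % source.n_lon
    i1 = (k + 1) % source.n_lon
    return i0, i1, np.clip(f, 0.0, 1.0)


def regrid(
    field: MonthlyField,
    target: RegularGrid,
    method: str = "bilinear",
    out: np.ndarray | None = None,
) -> MonthlyField:
    """Interpolate a gap-free field onto the target grid (same time axis).

    ``out`` optionally supplies a preallocated float64 output buffer.
    """
    if field.has_missing or field.missing_mask is not None:
        raise InputError("regrid requires a source field with no missing cells")
    if method == "nearest":
        return _regrid_nearest(field, target)
    if method != "bilinear":
        raise InputError(f"unknown regrid method {method!r}")

    j0, fy = _lat_weights(field.grid, target.lat_centers)
    i0, i1, fx = _lon_weights(field.grid, target.lon_centers)
    j1 = np.minimum(j0 + 1, field.grid.n_lat - 1)

    nt = field.time.n_months
    shape = (nt, target.n_lat, target.n_lon)
    if out is None:
        out = np.empty(shape)
    elif out.shape != shape or out.dtype != np.float64:
        raise InputError("out buffer must be float64 with the target field's shape")
    gy0, gy1 = (1.0 - fy)[None, :, None], fy[None, :, None]
    gx0, gx1 = (1.0 - fx)[None, None, :], fx[None, None, :]

    # separable two-stage interpolation: rows first, then columns; each
    # stage is a convex combination, so output stays within the bounds of
    # the 4 contributing source values.  Fixed scratch buffers + in-place
    # ufuncs keep temporaries off the allocator's hot path.
    chunk = min(nt, max(1, _CHUNK_VALUES // max(target.n_lat * field.grid.n_lon, 1)))
    ra = np.empty((chunk, target.n_lat, field.grid.n_lon))
    rb = np.empty_like(ra)
    ca = np.empty((chunk, target.n_lat, target.n_lon))
    cb = np.empty_like(ca)
    for t0 in range(0, nt, chunk):
        n = min(chunk, nt - t0)
        src = field.values[t0 : t0 + n]
        a, b, c, d = ra[:n], rb[:n], ca[:n], cb[:n]
        np.take(src, j0, axis=1, out=a)
        np.take(src, j1, axis=1, out=b)
        a *= gy0
        b *= gy1
        a += b  # rows interpolated in latitude
        np.take(a, i0, axis=2, out=c)
        np.take(a, i1, axis=2, out=d)
        c *= gx0
        d *= gx1
        c += d
        out[t0 : t0 + n] = c
    return MonthlyField(target, field.time, out)


def _regrid_nearest(field: MonthlyField, target: RegularGrid) -> MonthlyField:
    src = field.grid
    p = (target.lat_centers - src.lat_centers[0]) / src.lat_step
    j = np.clip(np.rint(p).astype(int), 0, src.n_lat - 1)
    d = (target.lon_centers - src.lon_centers[0]) % 360.0
    i = np.rint(d / src.lon_step).astype(int) % src.n_lon
    out = field.values[:, j[:, None], i[None, :]].copy()
    return MonthlyField(target, field.time, out)
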