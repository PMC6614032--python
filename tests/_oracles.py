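"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the library's vectorized code paths: plain
Python loops, explicit neighbor searches, and the textbook weight
formulas, so agreement with the package is a genuine cross-check.
"""
from __future__ import annotations

import math

EARTH_RADIUS_KM = 6371.0088


def cell_by_scan(grid, lat: float, lon: float):
    """Find the containing cell by testing every cell's half-open interval."""
    lon = ((lon + 180.0) % 360.0) - 180.0
    for i in range(grid.n_lat):
        s = grid.lat_edge_south + i * grid.lat_step
        if not (s <= lat < s + grid.lat_step):
            continue
        for j in range(grid.n_lon):
            w = grid.lon_edge_west + j * grid.lon_step
            d = (lon - w) % 360.0
            if d < grid.lon_step:
                return (i, j)
    return None


def bilinear_point(field_values, source_grid, lat: float, lon: float) -> float:
    """4-neighbor bilinear interpolation of one 2-D field at one point.

    Explicit neighbor search over source cell centers with longitude
    wraparound and latitude clamping at the outermost center rows.
    """
    lats = [source_grid.lat_edge_south + source_grid.lat_step * (i + 0.5)
            for i in range(source_grid.n_lat)]
    lons = [source_grid.lon_edge_west + source_grid.lon_step * (j + 0.5)
            for j in range(source_grid.n_lon)]

    # latitude bracket (clamped)
    if lat <= lats[0]:
        j0lat, wlat = 0, 0.0
    elif lat >= lats[-1]:
        j0lat, wlat = len(lats) - 2, 1.0
    else:
        j0lat = max(i for i in range(len(lats)) if lats[i] <= lat)
        j0lat = min(j0lat, len(lats) - 2)
        wlat = (lat - lats[j0lat]) / source_grid.lat_step

    # longitude bracket (periodic): find the center at or west of lon
    d = ((lon - lons[0]) % 360.0) / source_grid.lon_step
    i0 = int(math.floor(d)) % source_grid.n_lon
    i1 = (i0 + 1) % source_grid.n_lon
    wlon = d - math.floor(d)

    f00 = field_values[j0lat, i0]
    f01 = field_values[j0lat, i1]
    f10 = field_values[j0lat + 1, i0]
    f11 = field_values[j0lat + 1, i1]
    return (
        (1 - wlat) * (1 - wlon) * f00
        + (1 - wlat) * wlon * f01
        + wlat * (1 - wlon) * f10
        + wlat * wlon * f11
    )


def haversine(lat1, lon1, lat2, lon2) -> float:
    p1, l1, p2, l2 = (math.radians(x) for x in (lat1, lon1, lat2, lon2))
    a = (
        math.sin((p2 - p1) / 2.0) ** 2
        + math.cos(p1) * math.cos(p2) * math.sin((l2 - l1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * math.asin(math.sqrt(min(a, 1.0)))


def nearest_land_scan(grid, is_land, lat: float, lon: float):
    """Exhaustive great-circle scan over every land cell; ties break to the
    lowest latitude index, then lowest longitude index."""
    best = None
    best_d = None
    for i in range(grid.n_lat):
        ci = grid.lat_edge_south + grid.lat_step * (i + 0.5)
        for j in range(grid.n_lon):
            if not is_land[i, j]:
                continue
            cj = grid.lon_edge_west + grid.lon_step * (j + 0.5)
            d = haversine(lat, lon, ci, cj)
            if best_d is None or d < best_d:
                best, best_d = (i, j), d
    return best
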