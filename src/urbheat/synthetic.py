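"""Synthetic stand-ins for the pipeline's external inputs.

Generates (a) GCM-like monthly temperature fields on native model grids,
(b) a CRU-like observational reference field on the analysis grid with
ocean cells masked, (c) land-sea masks, and (d) a stratified city table
— all with a known ground truth so every pipeline stage is verifiable at
desk scale.

The generative equation for a grid cell at latitude ``lat`` in calendar
month ``m`` of year ``y`` under scenario ``s`` for model ``k`` is::

    T = mu(lat) + A(lat) * cos(2*pi*(m - phi(lat))/12)
        + delta_2100[s] * g_s(y) * amp(lat)
        + b_k + eps,     eps ~ N(0, noise_sd^2) iid

with the seasonal phase ``phi`` offset by 6 months across the equator,
``g_s`` a non-decreasing scenario trajectory that is exactly 0 through
1990, ``amp`` a latitude-amplification profile (>= 1 poleward, 1 at the
equator), and ``b_k`` a per-model constant bias (stationary by
construction, mirroring the delta method's core assumption).

Because the injected warming is linear in ``amp``, the change any
linear regridding-plus-averaging pipeline should recover at a target
cell has a closed form; :meth:`SyntheticTruth.expected_change` and
:meth:`SyntheticTruth.expected_ensemble_change` compute it, the latter
accounting for the 1-D latitude interpolation of ``amp`` from each
model's native grid (computed independently of the regrid module).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ConfigError, InputError
from .grid import LandMask, MonthTime, MonthlyField, RegularGrid
from .strata import ECOREGION_DOMAINS, GNI_BANDS, MIN_CITY_POPULATION, WHO_REGIONS


# ---------------------------------------------------------------------------
# scenario trajectories
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class Trajectory:
    """Warming trajectory g(year) in [0, 1], zero at and before ``start_year``.

    kind "ramp": linear rise from start to end, then plateau (strong
    mitigation, stabilizing forcing).  kind "accel": quadratic rise
    reaching 1 at ``end_year`` (unabated, accelerating forcing).
    """

    kind: str
    start_year: int
    end_year: int

    def __post_init__(self):
        if self.kind not in ("ramp", "accel"):
            raise ConfigError(f"unknown trajectory kind {self.kind!r}")
        if self.end_year <= self.start_year:
            raise ConfigError("trajectory end must be after start")

    def g(self, years) -> np.ndarray:
        y = np.asarray(years, dtype=float)
        x = np.clip((y - self.start_year) / (self.end_year - self.start_year), 0.0, 1.0)
        return x if self.kind == "ramp" else x ** 2

    def mean_g(self, first_year: int, last_year: int) -> float:
        return float(self.g(np.arange(first_year, last_year + 1)).mean())


DEFAULT_SCENARIOS: Dict[str, Trajectory] = {
    # "low": rises then plateaus mid-century (RCP2.6-like shape)
    "low": Trajectory("ramp", 2000, 2045),
    # "high": accelerating through 2100 (RCP8.5-like shape)
    "high": Trajectory("accel", 1990, 2100),
}


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------
@dataclass
class SyntheticTruth:
    """All parameters of the synthetic climate, with closed-form expectations."""

    scenarios: Dict[str, Trajectory] = dc_field(
        default_factory=lambda: dict(DEFAULT_SCENARIOS)
    )
    # end-of-century warming scale (degC) at the equator per scenario
    delta_2100: Dict[str, float] = dc_field(
        default_factory=lambda: {"low": 1.10, "high": 4.15}
    )
    # amp(lat) = 1 + amp_coef * (|lat|/90)**amp_power
    amp_coef: float = 1.5
    amp_power: float = 1.5
    # mu(lat) = mu_pole + (mu_equator - mu_pole) * cos(lat)
    mu_equator: float = 27.0
    mu_pole: float = -18.0
    # A(lat) = amp_max * |sin(lat)|; phase = month of seasonal peak
    seasonal_amp_max: float = 15.0
    phase_north: int = 7  # July peak in the northern hemisphere
    model_biases: Dict[str, float] = dc_field(default_factory=dict)
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not self.scenarios:
            raise ConfigError("at least one scenario required")
        for name, traj in self.scenarios.items():
            if name not in self.delta_2100 and name != "historical":
                raise ConfigError(f"no delta_2100 for scenario {name!r}")
            g = traj.g(np.arange(1901, 2101))
            if np.any(np.diff(g) < -1e-12):
                raise ConfigError(f"trajectory {name!r} is not non-decreasing")
            if abs(float(traj.g(1990))) > 1e-12:
                raise ConfigError(f"trajectory {name!r} must be 0 through 1990")
        lows = [v for k, v in self.delta_2100.items() if k in self.scenarios]
        if any(v <= 0 for v in lows):
            raise ConfigError("delta_2100 values must be positive")
        if "low" in self.delta_2100 and "high" in self.delta_2100:
            if not self.delta_2100["high"] > self.delta_2100["low"]:
                raise ConfigError("delta_2100['high'] must exceed delta_2100['low']")

    # -- profile pieces --------------------------------------------------
    def delta(self, scenario: str) -> float:
        if scenario == "historical" and "historical" not in self.delta_2100:
            # pathways share their historical forcing scale
            return self.delta_2100["high"]
        if scenario not in self.delta_2100:
            raise ConfigError(f"no delta_2100 for scenario {scenario!r}")
        return self.delta_2100[scenario]

    def trajectory(self, scenario: str) -> Trajectory:
        if scenario == "historical":
            # historical forcing shared by all pathways; pre-2014 the
            # pathways coincide, and the accelerating shape is 0 through 1990
            return self.scenarios.get("historical", self.scenarios["high"])
        if scenario not in self.scenarios:
            raise ConfigError(f"unknown scenario {scenario!r}")
        return self.scenarios[scenario]

    def amplification(self, lat) -> np.ndarray:
        lat = np.asarray(lat, dtype=float)
        return 1.0 + self.amp_coef * (np.abs(lat) / 90.0) ** self.amp_power

    def seasonal_mean(self, lat) -> np.ndarray:
        lat = np.asarray(lat, dtype=float)
        return self.mu_pole + (self.mu_equator - self.mu_pole) * np.cos(np.radians(lat))

    def seasonal_amplitude(self, lat) -> np.ndarray:
        lat = np.asarray(lat, dtype=float)
        return self.seasonal_amp_max * np.abs(np.sin(np.radians(lat)))

    def seasonal_phase(self, lat) -> np.ndarray:
        """Month of the seasonal peak: opposite hemispheres differ by 6."""
        lat = np.asarray(lat, dtype=float)
        south = (self.phase_north - 7) % 12 + 1
        return np.where(lat >= 0.0, float(self.phase_north), float(south))

    def climatology(self, lat, month) -> np.ndarray:
        """Stationary part mu + A cos(2 pi (m - phi)/12) (degC)."""
        lat = np.asarray(lat, dtype=float)
        month = np.asarray(month, dtype=float)
        phi = self.seasonal_phase(lat)
        return self.seasonal_mean(lat) + self.seasonal_amplitude(lat) * np.cos(
            2.0 * np.pi * (month - phi) / 12.0
        )

    def warming(self, lat, scenario: str, years) -> np.ndarray:
        return (
            self.delta(scenario)
            * self.trajectory(scenario).g(years)
            * self.amplification(lat)
        )

    # -- closed-form expectations ----------------------------------------
    def expected_change(
        self,
        lat,
        scenario: str,
        baseline: Tuple[int, int] = (1988, 2017),
        future: Tuple[int, int] = (2071, 2100),
    ) -> np.ndarray:
        """Injected change in period-mean temperature at a latitude.

        Uniform across calendar months, so it equals the annual-,
        hottest- and coldest-month change alike.
        """
        traj = self.trajectory(scenario)
        dg = traj.mean_g(*future) - traj.mean_g(*baseline)
        return self.delta(scenario) * dg * self.amplification(lat)

    def amplification_interp(self, lat: float, source_grid: RegularGrid) -> float:
        """amp(lat) as seen through linear interpolation in latitude
        between the bracketing source-grid cell centers (clamped at the
        outermost centers) — the value a center-anchored linear regridding
        transports to a target cell."""
        centers = source_grid.lat_centers
        p = (lat - centers[0]) / source_grid.lat_step
        p = min(max(p, 0.0), float(len(centers) - 1))
        j = min(int(math.floor(p)), len(centers) - 2)
        f = min(max(p - j, 0.0), 1.0)
        a = self.amplification(centers[j : j + 2])
        return float((1.0 - f) * a[0] + f * a[1])

    def expected_ensemble_change(
        self,
        cell_lat: float,
        scenario: str,
        source_grids: Sequence[RegularGrid],
        baseline: Tuple[int, int] = (1988, 2017),
        future: Tuple[int, int] = (2071, 2100),
    ) -> float:
        """Closed-form ensemble-mean change at a target cell center,
        averaging each model's latitude-interpolated amplification."""
        traj = self.trajectory(scenario)
        dg = traj.mean_g(*future) - traj.mean_g(*baseline)
        amps = [self.amplification_interp(cell_lat, g) for g in source_grids]
        return self.delta(scenario) * dg * float(np.mean(amps))

    # -- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "scenarios": {
                k: {"kind": t.kind, "start_year": t.start_year, "end_year": t.end_year}
                for k, t in self.scenarios.items()
            },
            "delta_2100": dict(self.delta_2100),
            "amp_coef": self.amp_coef,
            "amp_power": self.amp_power,
            "mu_equator": self.mu_equator,
            "mu_pole": self.mu_pole,
            "seasonal_amp_max": self.seasonal_amp_max,
            "phase_north": self.phase_north,
            "model_biases": dict(self.model_biases),
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        d = dict(d)
        d["scenarios"] = {k: Trajectory(**v) for k, v in d.get("scenarios", {}).items()}
        return cls(**d)


def default_truth(
    model_ids: Iterable[str], noise_sd: float = 0.5, seed: int = 0
) -> SyntheticTruth:
    """Truth with per-model biases spread deterministically over [-2, 2] degC."""
    model_ids = list(model_ids)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB1A5]))
    biases = {m: float(b) for m, b in zip(model_ids, rng.uniform(-2.0, 2.0, len(model_ids)))}
    return SyntheticTruth(model_biases=biases, noise_sd=noise_sd, seed=seed)


# ---------------------------------------------------------------------------
# fields
# ---------------------------------------------------------------------------
_NOISE_CHUNK = 4_000_000


def _simulate(
    grid: RegularGrid,
    scenario: str,
    truth: SyntheticTruth,
    years: Tuple[int, int],
    bias: float,
    noise_sd: float,
    rng: np.random.Generator,
    out: Optional[np.ndarray] = None,
) -> MonthlyField:
    time = MonthTime.from_years(*years)
    shape = (time.n_months, grid.n_lat, grid.n_lon)
    if out is None:
        values = np.empty(shape)
    else:
        if out.shape != shape or out.dtype != np.float64:
            raise InputError("out buffer must be float64 with the field's shape")
        values = out
    lats = grid.lat_centers
    # stationary climatology, (12, n_lat)
    clim = np.stack([truth.climatology(lats, m) for m in range(1, 13)])
    # warming term, (n_months, n_lat)
    g = truth.trajectory(scenario).g(time.years)
    warm = truth.delta(scenario) * np.outer(g, truth.amplification(lats))
    base = clim[time.months - 1] + warm + bias  # (n_months, n_lat)
    values[:] = base[:, :, None]
    if noise_sd > 0:
        # chunked so the normal draws reuse one small scratch buffer
        flat = values.reshape(-1)
        nbuf = np.empty(min(_NOISE_CHUNK, flat.size))
        for s in range(0, flat.size, _NOISE_CHUNK):
            b = nbuf[: min(_NOISE_CHUNK, flat.size - s)]
            rng.standard_normal(out=b)
            b *= noise_sd
            flat[s : s + b.size] += b
    return MonthlyField(grid, time, values)


def simulate_model_field(
    grid: RegularGrid,
    scenario: str,
    model_id: str,
    truth: SyntheticTruth,
    years: Tuple[int, int] = (1901, 2100),
    seed=None,
    out: Optional[np.ndarray] = None,
) -> MonthlyField:
    """One GCM-like global field on its native grid (no missing cells).

    ``out`` optionally supplies a preallocated float64 value buffer.
    """
    if scenario not in truth.scenarios:
        raise ConfigError(f"unknown scenario {scenario!r}")
    if model_id not in truth.model_biases:
        raise ConfigError(f"unknown model {model_id!r} (no bias configured)")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    return _simulate(
        grid, scenario, truth, years, truth.model_biases[model_id], truth.noise_sd, rng,
        out=out,
    )


def simulate_reference_field(
    grid: RegularGrid,
    truth: SyntheticTruth,
    years: Tuple[int, int] = (1901, 2013),
    mask: Optional[LandMask] = None,
    seed=None,
    noise_sd: Optional[float] = None,
) -> MonthlyField:
    """CRU-like observational reference: unbiased truth (b = 0) under the
    shared historical trajectory, with ocean cells missing per the mask."""
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    sd = truth.noise_sd if noise_sd is None else noise_sd
    fld = _simulate(grid, "historical", truth, years, 0.0, sd, rng)
    if mask is not None:
        if mask.grid != grid:
            raise InputError("mask grid differs from field grid")
        fld.values[:, ~mask.is_land] = np.nan
        fld.missing_mask = ~mask.is_land
    return fld


# ---------------------------------------------------------------------------
# land masks
# ---------------------------------------------------------------------------
def make_land_mask(
    grid: RegularGrid,
    mode: str = "random-blobs",
    seed=None,
    land_fraction: float = 0.3,
) -> LandMask:
    """Deterministic synthetic land-sea masks.

    "all-land": every cell land.  "latband-continents": fixed continent-like
    longitude bands between 60S and 75N.  "random-blobs": contiguous blobs
    from thresholding smoothed noise at the requested land fraction.
    """
    if mode == "all-land":
        return LandMask(grid, np.ones(grid.shape, dtype=bool))
    if mode == "latband-continents":
        lat = grid.lat_centers[:, None]
        lon = grid.lon_centers[None, :]
        bands = (
            ((lon >= -170) & (lon <= -30))
            | ((lon >= -20) & (lon <= 55))
            | ((lon >= 60) & (lon <= 180))
        )
        return LandMask(grid, bands & (lat >= -60) & (lat <= 75))
    if mode == "random-blobs":
        if not (0.0 < land_fraction <= 1.0):
            raise ConfigError("land_fraction must be in (0, 1]")
        rng = np.random.default_rng(seed)
        noise = rng.normal(size=grid.shape)
        sigma = max(min(grid.n_lat, grid.n_lon) / 12.0, 1.0)
        smooth = gaussian_filter(noise, sigma=sigma, mode=("nearest", "wrap"))
        thresh = np.quantile(smooth, 1.0 - land_fraction)
        is_land = smooth >= thresh
        if not is_land.any():  # degenerate tiny grids
            is_land.flat[int(np.argmax(smooth))] = True
        return LandMask(grid, is_land)
    raise ConfigError(f"unknown mask mode {mode!r}")


# ---------------------------------------------------------------------------
# city table
# ---------------------------------------------------------------------------
#  default stratum proportions loosely shaped like the study sample
DEFAULT_STRATA = {
    "ecoregion_domain": {
        "polar": 0.04,
        "humid temperate": 0.45,
        "dry": 0.14,
        "humid tropical": 0.37,
    },
    "who_region": {
        "Africa": 0.08,
        "Americas": 0.23,
        "Eastern Mediterranean": 0.08,
        "Europe": 0.22,
        "South-East Asia": 0.16,
        "Western Pacific": 0.23,
    },
    "gni_stratum": {"<1045": 0.15, "1045-4125": 0.25, "4125-12746": 0.30, ">12746": 0.30},
}

#  latitude bands (absolute latitude) consistent with each ecoregion domain
_DOMAIN_LAT_BANDS = {
    "polar": (55.0, 75.0),
    "humid temperate": (30.0, 60.0),
    "dry": (15.0, 45.0),
    "humid tropical": (0.0, 23.5),
}
_P_NORTH = 0.7  # most cities sit in the northern hemisphere


def _quota_counts(n: int, proportions: Dict[str, float]) -> Dict[str, int]:
    """Largest-remainder allocation of n among categories."""
    cats = list(proportions)
    exact = np.array([proportions[c] * n for c in cats])
    base = np.floor(exact).astype(int)
    rem = n - int(base.sum())
    order = np.argsort(-(exact - base), kind="stable")
    for k in order[:rem]:
        base[k] += 1
    return dict(zip(cats, base.tolist()))


def _allocate(n: int, proportions: Dict[str, float], rng) -> np.ndarray:
    counts = _quota_counts(n, proportions)
    labels = np.repeat(list(counts.keys()), list(counts.values()))
    return rng.permutation(labels)


def generate_city_table(
    n: int, strata_config: Optional[dict] = None, seed=None
) -> pd.DataFrame:
    """A stratified random sample of synthetic cities.

    Each stratification axis is allocated by largest-remainder quotas on
    the configured proportions and randomly paired, so realized counts
    track proportions exactly (to integer rounding).  City latitude is
    drawn inside the band consistent with its ecoregion domain.
    """
    if n < 0:
        raise ConfigError("n must be non-negative")
    cfg = {k: dict(v) for k, v in DEFAULT_STRATA.items()}
    if strata_config:
        for axis, props in strata_config.items():
            if axis not in cfg:
                raise ConfigError(f"unknown stratification axis {axis!r}")
            cfg[axis] = dict(props)
    valid = {
        "ecoregion_domain": ECOREGION_DOMAINS,
        "who_region": WHO_REGIONS,
        "gni_stratum": GNI_BANDS,
    }
    for axis, props in cfg.items():
        unknown = set(props) - set(valid[axis])
        if unknown:
            raise ConfigError(f"unknown categories {unknown} on axis {axis!r}")
        if any(p < 0 for p in props.values()) or abs(sum(props.values()) - 1.0) > 1e-8:
            raise ConfigError(f"proportions on axis {axis!r} must be >=0 and sum to 1")

    cols = {
        "city_id": [f"c{i:04d}" for i in range(n)],
        "name": [f"City{i:04d}" for i in range(n)],
    }
    rng = np.random.default_rng(seed)
    domains = _allocate(n, cfg["ecoregion_domain"], rng)
    regions = _allocate(n, cfg["who_region"], rng)
    gni = _allocate(n, cfg["gni_stratum"], rng)

    lats = np.empty(n)
    for i, d in enumerate(domains):
        lo, hi = _DOMAIN_LAT_BANDS[str(d)]
        a = rng.uniform(lo, hi)
        hemi = 1.0 if rng.random() < _P_NORTH else -1.0
        lats[i] = hemi * a
    lons = rng.uniform(-180.0, 180.0, n)
    lons[lons >= 180.0] = -180.0
    log_pop = rng.uniform(np.log10(MIN_CITY_POPULATION), np.log10(2.0e7), n)
    pop = np.maximum(np.round(10.0 ** log_pop).astype(int), MIN_CITY_POPULATION)

    df = pd.DataFrame(
        {
            **cols,
            "lat": np.round(lats, 4),
            "lon": np.round(lons, 4),
            "population": pop,
            "gni_stratum": gni,
            "ecoregion_domain": domains,
            "who_region": regions,
        }
    )
    return df


#  native-grid shapes (n_lat, n_lon) of the 18-model CMIP5 monthly-temperature
#  ensemble generation, spanning 64x128 up to 192x320-class resolutions
CMIP5_GRID_SHAPES = {
    "CCSM4": (192, 288),
    "CNRM-CM5": (128, 256),
    "CSIRO-Mk3-6-0": (96, 192),
    "CanESM2": (64, 128),
    "GFDL-CM3": (90, 144),
    "GFDL-ESM2G": (90, 144),
    "HadGEM2-ES": (145, 192),
    "IPSL-CM5A-LR": (96, 96),
    "IPSL-CM5A-MR": (143, 144),
    "MIROC-ESM": (64, 128),
    "MIROC-ESM-CHEM": (64, 128),
    "MIROC5": (128, 256),
    "MPI-ESM-LR": (96, 192),
    "MPI-ESM-MR": (96, 192),
    "MRI-CGCM3": (160, 320),
    "NorESM1-M": (96, 144),
    "bcc-csm1-1": (64, 128),
    "bcc-csm1-1-m": (160, 320),
}
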