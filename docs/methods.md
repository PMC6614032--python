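# Methods

## The estimand and the processing chain

The pipeline estimates, for each city, scenario, and future period, the
change in 30-year-mean temperature relative to a baseline period — for
the annual mean, the hottest month, and the coldest month — averaged
over an ensemble of climate models. The chain is: native-grid monthly
model fields → bilinear regridding to a common grid → additive
("delta-method") bias adjustment against a reference climatology →
extraction at city grid cells → 30-year period climatologies → model
ensemble mean → future-minus-baseline changes → stratified summaries.

Working with *changes* rather than absolute temperatures, together with
the additive adjustment, makes every reported number invariant to
stationary model biases: the adjustment subtracts each model's
calibration-window climatology and adds the reference's, and any
time-constant offset cancels from the difference of two period means of
the same calendar months. This is an algebraic identity, not an
approximation, and the test suite checks it both as calibration closure
(adjusted 1961–1990 monthly means equal the reference's to ≤ 1e-9 °C)
and as end-to-end cancellation (adding 3.7 °C to an entire model series
leaves the final change table unchanged).

Assumptions worth stating explicitly:

- **Stationary bias.** Offsets estimated on 1961–1990 are applied to the
  whole 1901–2100 series. Non-stationary model error (e.g. a bias that
  grows with warming) is not corrected and would propagate into changes.
- **Point-sample interpolation.** Cell values are treated as point
  samples at cell centers; regridding is bilinear among the 4
  surrounding source centers with longitude wraparound, and target rows
  poleward of the outermost source center are clamped to the nearest
  source row rather than extrapolated. Conservative (area-weighted)
  remapping is out of scope.
- **Uniform calendar.** Twelve equal months, gap-free; real-GCM calendar
  variants (360-day etc.) are an ingest-adapter concern.
- **One cell per city.** No area- or population-weighted footprints.

## Grid and time conventions

Cells are half-open intervals `[edge, edge+step)` in both axes with the
value registered at the center; a point on a shared edge belongs to the
higher-index cell, which makes cell lookup total and deterministic. The
lookup is corrected against the exact interval arithmetic so it agrees
with brute-force interval membership even for points within one ulp of
an edge. Longitudes are stored in [−180, 180) and normalized on input.
The standard analysis grid is 0.5° × 0.5° global (360 × 720, centers at
−89.75…89.75 / −179.75…179.75, CRU-style); any global regular grid may
be configured instead.

The nearest-land rule for coastal cities minimizes great-circle
(haversine) distance between the city coordinate and land-cell centers
— index-space distance would be wrong near the poles. Exact distance
ties break to the lowest latitude index, then lowest longitude index.
The rule applies whenever a city's own cell is non-land, "coastal" being
simply the only way that arises.

## The synthetic world

The generator emulates the structure of a multi-model monthly
temperature archive with a known ground truth. A cell at latitude
`lat`, calendar month `m`, year `y`, scenario `s`, model `k`:

    T = mu(lat) + A(lat) cos(2π (m − φ(lat))/12)
        + delta_s · g_s(y) · amp(lat) + b_k + ε

| parameter | default | meaning |
|---|---|---|
| `mu(lat)` | −18 + 45 cos(lat) °C | annual-mean profile (27 °C equator, −18 °C poles) |
| `A(lat)` | 15 · \|sin(lat)\| °C | seasonal amplitude, zero at the equator |
| `φ(lat)` | month 7 (N) / 1 (S) | seasonal peak; hemispheres in phase opposition |
| `delta_s` | 1.10 (low), 4.15 (high) °C | end-of-century warming scale at the equator |
| `g_s(y)` | low: linear ramp 2000→2045 then plateau; high: quadratic 1990→2100 | non-decreasing trajectory, exactly 0 through 1990 |
| `amp(lat)` | 1 + 1.5 (\|lat\|/90)^1.5 | polar amplification, 1 at the equator |
| `b_k` | U(−2, 2) °C per model | stationary model bias |
| `ε` | N(0, 0.5²) °C i.i.d. | month-to-month noise |

The reference ("observed") field uses the same equation with `b = 0`
under the shared historical trajectory, with ocean cells masked; since
both trajectories are exactly zero through 1990, the 1961–1990
calibration climatology is scenario-free. Land-sea masks come in three
modes (all-land; fixed continent-like bands; random blobs from smoothed
noise thresholded at a requested land fraction). The city sample is
stratified by GNI band, ecoregion domain, and WHO region via
largest-remainder quotas (realized counts track the configured
proportions exactly, and small samples still contain polar cities),
with city latitude drawn inside the band consistent with its ecoregion
domain.

Because the injected warming is linear in `amp`, its transport through
any center-anchored linear interpolation has a closed form: at a target
cell the recovered ensemble annual change is

    delta_s · (ḡ_future − ḡ_baseline) · mean_k amp_interp_k(lat_cell)

where `amp_interp_k` is the 1-D linear interpolation of `amp` between
the bracketing latitude centers of model k's native grid (clamped at the
outermost rows). `SyntheticTruth.expected_ensemble_change` computes
this independently of the 2-D regrid code and is the oracle for the
recovery tests: noiseless runs agree to ≤ 1e-9 °C; with 0.5 °C monthly
noise, a 6-model × 360-month mean difference has standard error
≈ 0.015 °C, and every city's estimate falls within ±0.1 °C of truth.

Note that `delta_s` scales the trajectory, so the *realized*
equator-level change between the 1988–2017 and 2071–2100 windows is
`delta_s · (ḡ_future − ḡ_baseline)` — slightly below `delta_s` for the
low pathway (its ramp has already begun during the baseline) and about
0.74 · `delta_s` for the accelerating high pathway.

What the generator does **not** emulate — and hence what passing tests
do not establish about real archives: temporal autocorrelation and modes
of variability (irrelevant to 30-year-mean recovery at the tested
tolerance, but real uncertainties would be larger), non-stationary model
biases, changes in seasonal amplitude or higher moments under warming
(a "seasonal sharpening" of the tails is deliberately absent: the
method's 30-year monthly means are insensitive to tail behavior),
realistic coastlines and orography, and real-calendar bookkeeping.

## Numerical choices

- All field arithmetic in float64; persisted tables are written at
  1e-6 °C precision, so outputs are bitwise reproducible and sub-nano
  rounding noise cannot masquerade as signal.
- Bilinear regridding is separable (latitude pass then longitude pass,
  each a convex combination), so outputs are bounded by the four
  contributing source values; chunked evaluation reuses fixed scratch
  buffers, and the pipeline reuses one native-field and one
  analysis-grid buffer across model × scenario passes (page-fault cost
  of reallocating ~100 MB fields dwarfs the arithmetic).
- Monthly-mean extremes: ties go to the lowest month index. Hottest and
  coldest months are identified per period by default (the hottest month
  may shift between baseline and future); `extreme_mode =
  "fixed_baseline"` instead reads the future value at the baseline's
  extreme months. The ensemble is formed on monthly climatologies
  before extreme identification by default (averaging extremes picked
  in different months across models would mix seasons);
  `ensemble_ordering = "extremes_first"` averages per-model extreme
  values for sensitivity analysis. In the noiseless synthetic world the
  two orderings coincide (all models share the seasonal shape), which
  the suite asserts.
- Exceedance thresholds use strict `>` by default ("greater than 2 °C",
  "exceed 40 °C"); the comparison operator is configurable since
  boundary handling is a reporting convention.
- Cells missing in the reference propagate missing offsets and missing
  adjusted values rather than falling back to unadjusted data; an
  extraction that lands on a missing cell is a hard error naming the
  city and cell.
- Cities lacking an attribute are excluded per analysis (logged), never
  globally.
- Reproducibility: one root seed; every random stage draws from a named
  `SeedSequence` child, so identical config + seed gives byte-identical
  manifests and CSVs, and the manifest alone suffices to re-run.

## Problem sizes

The desk-scale study configuration used by the analysis scripts, the
test suite, and the acceptance script is: 6 models with native grids
32×64 … 64×128 (scaled-down analogues of the archive's resolution
spread; the generator and regridder handle full-size native grids up to
192×320, which the tests exercise over short year ranges), a 4° × 4°
analysis grid, 2 scenarios, 50 cities, monthly series 1901–2100. The
recovery, closure, cancellation, ordering, and determinism properties
are resolution-independent; the 0.5° standard grid is exercised
directly in the geometry and regridding tests.

## Known limitations

- The additive delta method corrects means only; variance and
  distribution-shape biases persist (quantile mapping is out of scope).
- Monthly 30-year means carry no information about daily extremes,
  heatwaves, humidity, or urban-heat-island effects.
- Synthetic WHO regions are sampled independently of city longitude, so
  region labels partition the sample but are not geographically faithful.
- The NetCDF adapter expects CF-style lat/lon/time fields with the
  package's integer month-index convention (or plain kelvin/celsius
  variables); decoding native GCM calendars is out of scope.
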