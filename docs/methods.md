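# Methods

This note documents the models, definitions and numerical choices behind
`heatrun`, and what the synthetic-data tests do and do not establish about
real data.

## Heatwave definition

A heatwave at a grid cell is a maximal run of at least `min_run_days`
(default 3) consecutive days with daily maximum temperature (Tmax) strictly
above the cell's percentile threshold. Thresholds are empirical per-cell
quantiles (95th, 97.5th, 99th) of daily values over a fixed reference
period, 1961–1990 by default (the WMO climate-normal window). Two modes are
computed:

- **day**: Tmax above its threshold;
- **day_night**: Tmax above its Tmax threshold *and* Tmin above its Tmin
  threshold on the same days. Day–night exceedance days are a subset of day
  exceedance days at equal percentiles, so day–night events nest inside day
  events; several invariant tests rely on this.

Choices a one-line definition leaves open, each exposed as configuration:

- **Quantile pool** (`threshold_pool`): default `pooled` uses every
  reference-period day at a cell. In a weakly seasonal tropical domain
  (annual Tmax range under 3 °C) the pooled quantile is dominated by the
  warm season, which is exactly the regime where heat stress occurs. A
  `doy_window` variant (±7-day circular calendar window) is available for
  sensitivity analysis.
- **Quantile definition**: linear interpolation between order statistics
  (`numpy.percentile` default), fixed for bit-reproducibility.
- **Inequality**: strict (`>`), so a constant series never exceeds its own
  quantile.
- **Run breaking**: any non-exceedance or missing day ends a run; runs never
  bridge gaps.
- **Year attribution**: an event belongs to the year of its start day.
- **Missing data**: cells with more than `max_missing_fraction` (default
  10%) missing reference days get undefined thresholds and are excluded,
  with a logged count.

The Malaysian operational alert levels are a separate absolute-threshold
classifier on 3-day windows of Tmax: with m the minimum of the three days,
level 1 (Alert) for m ∈ [35, 37) °C, level 2 for m ∈ [37, 40] °C, level 3
for m > 40 °C, else 0. The nominal band edges overlap at 37 °C; the boundary
is assigned to the higher band.

## Annual indices

Per year and percentile, from the per-cell event list:

| index | definition | unit |
|---|---|---|
| AHW | land area hosting ≥1 day-mode event | km² |
| DHW | maximum day-mode event duration | days |
| THW | maximum daily Tmax over day-mode event days | °C |
| CTHW | Σ (Tmax − threshold) over day-mode event days | °C |
| HWI | Σ over day-mode events of the event cell's land-area fraction | – |
| AHWN | area with ≥1 day–night event, as % of land area | % |
| DHWN / THWN / CTHWN | as DHW/THW/CTHW for day–night events | |

Design points worth stating explicitly:

- **Events are per cell.** No spatial merging of neighbouring cells into a
  single synoptic "event" is attempted; an episode covering k cells counts
  k events. HWI depends directly on this count: it equals the affected area
  fraction summed over events (equivalently, mean affected fraction ×
  event count) and lies in [0, n_events].
- **THW** uses the maximum peak over events by default; a mean variant is
  selectable (`thw_stat="mean"`). **CTHW** sums exceedance above the
  threshold rather than raw Tmax because exceedance is comparable across
  cells with different climatologies; both aggregations are defensible
  readings of "cumulative temperature during heatwaves".
- Zero-event years report all indices as 0 with an explicit flag, and the
  annual series always includes them, so trend tests see the full record.
- Because the plausible scale of an affected-area trend depends on whether
  areas are measured in km², affected-cell counts, or fractions, the annual
  table also carries `AHW_cells` (count) and `AHWN_km2` alongside the
  canonical columns.

Cell areas are spherical-Earth band areas, R²·Δλ·(sin φ_top − sin φ_bot)
with R = 6371 km; at 0.25° resolution near the equator a cell is ≈ 772.8
km². Summing all 0.25° cells over the globe reproduces 4πR² to < 0.1%
(tested).

## Trend analysis: Sen's slope and the Mann–Kendall test under scaling

Sen's slope is the median of all pairwise slopes (y_j − y_i)/(j − i), with
the usual odd/even median rule; decadal change is 10 × the per-step slope.
The Mann–Kendall statistic is S = Σ_{i<j} sign(y_j − y_i) with classical
variance var₀(S) = [n(n−1)(2n+5) − Σ_ties t(t−1)(2t+5)]/18 and a continuity
correction: Z = (S−1)/√var for S > 0, (S+1)/√var for S < 0, 0 at S = 0.

Climatic series exhibit long-term persistence (LTP): under fractional
Gaussian noise with Hurst exponent H, the lag-l autocorrelation is

ρ_l = ½(|l+1|^{2H} − 2|l|^{2H} + |l−1|^{2H}),

and the classical variance badly understates var(S), producing spurious
trends. The modified test proceeds as follows (the likelihood-based LTP
procedure implemented by `HKprocess::MannKendallLTP` in R):

1. de-trend the series with its Sen slope;
2. map the de-trended values to normal scores of ranks, Φ⁻¹(rank/(n+1));
3. estimate H by maximising the Gaussian log-likelihood
   −½ log|C_n(H)| − zᵀC_n(H)⁻¹z / (2γ₀) over H ∈ (0.5, 0.98) by bounded
   scalar search (tolerance 1e-4), where C_n(H) is the fGn correlation
   matrix. A perfectly linear series leaves constant residuals; H is then
   reported as 0.5 and not significant.
4. test Ĥ one-sided against its white-noise null distribution, using the
   empirical moments μ_H(n) = 0.5 − 2.87 n^−0.9067 and
   σ_H(n) = 0.77654 n^−½ − 0.0062 (only H > ½ inflates var(S), hence
   one-sided);
5. if H is significant, compute the scaled variance as the quadruple sum
   over index pairs (i<j, k<l) of (2/π) arcsin of the fGn correlation
   contrast, multiplied by the empirical bias-correction polynomial
   B(Ĥ, n) that compensates for plugging in an *estimated* H (the
   correction can be disabled for sensitivity checks);
6. otherwise keep the classical variance. Both the classical and the
   LTP-corrected Z/p are always reported, since operational practice
   differs on whether the correction should be conditional.

Numerics: for a gap-free series the quadruple sum is grouped by index
differences (a, b, c), reducing O(n⁴) arcsin evaluations to O(n³); the
grouped and direct forms agree to 1e-10 and both match a four-index brute
force (tested). At H = ½ the sum collapses to var₀ exactly through the
arcsine identity, which is the basis of the reduction test. Missing years
are handled pairwise: statistics use the available points at their original
time indices. Arguments to arcsin are clipped to [−1, 1]; a numerically
non-positive variance is floored at var₀ with a warning.

Simulation-based calibration (in the test suite, fixed seeds): on iid
Gaussian noise at n = 73 the modified test rejects at 4–5% (2,000
replicates, nominal 5%); on trend-free fGn with H = 0.8 the classical test
rejects at ≈ 37% while the modified test stays near 11%, i.e. the
correction removes most of the spurious-trend rate. Ĥ recovery on fGn
(H = 0.8, n = 1000) has mean absolute error ≈ 0.03.

No multiple-testing correction is applied across the 27 cells of the trend
table; α = 0.05 throughout.

## Synthetic data generator

The generator emulates the statistical features the analysis relies on, for
a humid-tropical domain:

- **Seasonal cycle**: 12 monthly means for Tmax and Tmin. Defaults anchor
  the observed extremes of Peninsular Malaysia's cycle — Tmax lowest in
  December (28.1 °C), highest in April (30.8 °C); Tmin lowest in January
  (21.8 °C), highest in May (23.3 °C) — with the intermediate months filled
  as a smooth cycle between those anchors (the full monthly table is not
  fixed by any single published number). Daily values interpolate the
  monthly means periodically at month midpoints (`seasonal_interp=
  "linear"`); a `"step"` variant holds each month constant, which is the
  mode under which "every December day equals the December mean" holds
  exactly.
- **Calendar**: 365-day no-leap calendar, removing leap-day special cases;
  the NetCDF reader preserves true calendars for real data.
- **Anomalies**: per-cell independent daily anomaly series, iid, AR(1)
  (φ default 0.6 — chosen as a plausible daily-temperature persistence for
  test purposes, not fitted to any observed record) or exact fractional
  Gaussian noise via Davies–Harte circulant embedding (Cholesky fallback if
  the embedding loses non-negative definiteness; the method used is
  recorded). Spatial correlation of anomalies is not modelled; an optional
  linear latitude gradient (default 0) stands in for spatial structure.
- **Tmin**: its own cycle + the cell's shared anomaly + an independent
  offset (sd `diurnal_offset_sd`, default 0.2 °C), clipped so Tmax ≥ Tmin.
- **Trend**: linear, `trend_per_decade` (default 0.18 °C/decade, the
  region's observed warming rate since the 1950s).
- **Injected events**: rectangular cell-day blocks of known location,
  start, duration and amplitude added to Tmax (optionally Tmin), returned
  with a ground-truth ledger for recovery tests.
- **Population**: clustered raster at `fine_factor` × the temperature
  resolution (Gaussian cluster kernels over a uniform floor), multinomial
  allocation so non-missing counts sum exactly to the configured total,
  with an optional missing-data fraction.

Everything is bit-reproducible from config + seed.

What passing on synthetic data shows — and does not. The tests establish
algorithmic correctness (oracle equivalence, conservation, nesting,
calibration under the stated noise models) and end-to-end recovery of known
signals. They do not establish that ERA5-like fields satisfy these noise
models, that real heatwaves are per-cell independent, or that the default
AR(1) persistence matches any observed record; conclusions about a real
domain require running the pipeline on real inputs.

The exact-recovery test deserves a note: a percentile threshold guarantees
exceedance days exist, and with a seasonal cycle those days cluster in the
warm season where natural ≥3-day runs arise — which are genuine heatwaves
under the definition, not detector errors. The recovery fixture therefore
uses a flat annual cycle with iid noise (sd 0.5 °C) against 8 °C injected
events, where the expected number of natural runs is ≈ 0.05 per realisation
and the recovered event set equals the ground truth exactly.

## I/O and formats

Temperature cubes are CF-style NetCDF (time/lat/lon; °C, or auto-converted
from kelvin via the units attribute; descending latitudes are normalised to
ascending with fields flipped accordingly). Population rasters are ESRI
ASCII grids with a NODATA sentinel mapped to missing. Aggregation of a fine
population raster onto the analysis grid is an area-weighted overlap sum —
separable in latitude/longitude for axis-aligned cells — that skips missing
fine cells and reduces to an exact block sum for nested grids; it conserves
the global total exactly in the nested case and to 1e-6 relative otherwise
(tested against a rectangle-intersection oracle). Tables are CSV at 17
significant digits, which round-trips doubles losslessly.

## Exposure

A person counts as affected in a year if their cell hosted at least one
event of the chosen percentile/mode (day mode by default; the published
exposure maps are phrased in terms of Tmax thresholds); a person-days
variant weights by event duration. Population years are matched exactly by
default, with an optional logged nearest-year fallback. Affected plus
unaffected population equals the total, and exposure is non-increasing in
the percentile.

## Problem sizes used in the test suite

Synthetic cubes of 32–73 years on 2×2 to 4×4 grids at 0.25°, chosen so the
full suite exercises the complete pipeline — including the 2,000-replicate
type-I calibration and 200-replicate Hurst-recovery simulations — in a few
minutes on one CPU. The statistics involved (per-cell quantiles, run
extraction, pairwise trend tests) are embarrassingly parallel across cells,
so behaviour at these sizes is representative of larger grids.

## Known limitations

- Per-cell events only; no spatial clustering into synoptic events.
- No humidity/apparent-temperature definitions.
- Anomalies are spatially independent in the generator.
- The LTP null-distribution moments and bias polynomial are empirical
  large-sample fits; very short series (n < 10) fall back to the classical
  test.
- Geographic lat–lon grids only; masks must be supplied as boolean grids.
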