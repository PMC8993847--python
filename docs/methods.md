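# Methods

## The chill hazard model

The livestock chill index is an additive empirical heat-loss model,
`C = (11.7 + 3.1 v^0.5)(40 − T) + 481 + 418(1 − e^(−0.04R))` in kJ/m²/h.
Its structure matters for the analysis: the wind–temperature term is linear
in the temperature deficit below the 40 °C reference and concave in wind, so
`C` is monotone increasing in wind (for T ≤ 40), decreasing in temperature
and increasing in rain, with the rain contribution saturating at
418 kJ/m²/h — a day of 100 mm and a day of 250 mm contribute almost equally.
These monotonicities are verified by finite-difference sweeps in the tests.

Category boundaries are closed on the left: `C ≥ 1000` is "high" and
`C ≥ 1200` is "severe", so an operational alert fires at exactly the
published threshold.  Temperatures above the 40 °C reference are allowed
(the formula remains defined, and tropical summer inputs do exceed it) but
logged as a warning, since the index was designed for cold stress.  No
"moderate" band is implemented: its bounds are not defined anywhere we could
ground them, and guessing a boundary would be worse than omitting it.  Wind
measurement height (2 m station vs 10 m model winds) is treated as metadata
only; no height conversion is applied, matching how the index is used
operationally with both input types.

## Extremes as calendar-day percentiles

Fixed thresholds like 1000 kJ/m²/h encode a southern-Australia winter
baseline; for a tropical region the hazard is better defined relative to the
local annual cycle.  For each grid point and calendar day d, all values
within ±7 days of d (a 15-day window), pooled across every available year —
and across all ensemble members when the source is a hindcast — form the
sample from which the empirical q-quantile is taken.  The window serves two
purposes: it absorbs the seasonal cycle (each sample is locally stationary)
and multiplies the sample size (23 years × 11 members × 15 days = 3795
member-days per calendar day for a typical sub-seasonal hindcast set).

Numerical conventions, frozen for reproducibility:

- **Quantile rule**: linear interpolation between closest order statistics
  (numpy's default).  On a pooled sample of hundreds of values any
  alternative rule shifts thresholds by less than one inter-order-statistic
  spacing.
- **Leap days**: 29 February is folded onto 28 February (day 59 of a
  365-day calendar), so leap-day data is pooled rather than discarded and
  29 February inherits the 28 February threshold.
- **Year wrap**: the window wraps the December–January boundary; the target
  season (late January–early February) would otherwise be exactly the part
  of the year with truncated windows.
- **Ties**: exceedance is strict (`>` above, `<` below).  A value exactly at
  its threshold is not extreme, which makes the constant-field case
  unambiguous (no day of a constant record is extreme).
- **Area statistics**: cosine-latitude weighting.  Over an 8° × 5° box near
  20° S the effect is ~1%, but the choice is explicit and testable.
- **In-sample consistency**: on a long stationary record the fraction of
  day-cells exceeding the calendar-day 90th percentile converges to 10% —
  the climatological reference probability against which forecast
  probabilities are judged.  The acceptance script recomputes this on a
  30-year record.

Run statistics (`longest_run`) report the first maximal run of consecutive
exceedance days, its onset/offset dates inclusive (duration = offset − onset
+ 1) and optionally the peak value and date within the run.

## Ensemble probability of an extreme week

A lagged ensemble pools members from consecutive initialization dates,
trimmed to the common valid-time range; member counts add (33/day × 3 days
= 99) and no valid times are fabricated.  The default probability mode
compares each member's target-week mean with the week mean of the daily
thresholds and reports the exceeding-member fraction; a per-day counting
mode (mean daily member-exceedance fraction) is available and the choice is
recorded in the output provenance.  The weekly-mean mode was chosen as the
default because the product is a forecast *for the week*, and weekly
averaging filters the daily timing errors that dominate at sub-seasonal
leads; with strict exceedance it also has clean edge cases (forecast equal
to climatology → p = 0).

Calibration is empirical quantile–quantile matching per grid cell: a
forecast value x maps to F_obs⁻¹(F_model(x)) with both CDFs built by the
same linear-interpolation rule as the climatology thresholds.  The map is
monotone (member ranks preserved) and is the exact identity when the model
pool equals the observed pool; values outside the hindcast range are clamped
to the pool's end quantiles.  An optional calendar-day window restricts both
pools seasonally.  Calibration is applied to the daily input variables
before the chill index is computed, not to the index itself, preserving the
physical formula; the order is configurable in principle and recorded where
used.  Forecasts are matched to hindcast start dates by nearest calendar
distance, ties to the earlier date.

## MJO stall diagnostics

Phase is the octant of atan2(RMM2, RMM1) under the standard phase-diagram
layout (phase 1 begins at 180°, counterclockwise, half-open boundaries);
amplitude √(RMM1² + RMM2²) ≥ 1 counts as active, with the boundary value
active.  Residence time is the longest run of consecutive days with phase in
the target set (default {6, 7}); alternation within the set does not break a
run, inactive days do (by default — `require_active` is configurable), and
`max_gap_days` (default 0) can bridge short excursions for sensitivity
tests.  Members with residence ≥ 17 days are "stalled", < 13 days "fast",
and the [13, 17) band belongs to neither, so the subsets cannot overlap.

Composite MSLP anomalies are taken against a calendar-day mean climatology
smoothed with a centered 11-day running mean that wraps the year boundary
(an 11-day boxcar attenuates an annual-cycle sinusoid by < 0.2%, so the
smoothing is essentially transparent to the seasonal cycle while damping
day-to-day sampling noise).  The "weighted" multi-model composite gives each
model equal weight: within a model the subset members are averaged, then
models contributing at least one member are averaged equally, then the
result is averaged over the composite window.  This prevents large-ensemble
models from dominating; subset sizes per model are reported in the output
attributes.  Other weightings (per-member, skill-weighted) are defensible;
equal-per-model is the package's choice and is recorded in provenance.

## The synthetic-data generator

The generator emulates the study conditions, not the dynamics, of a
tropical-Australia compound chill event:

- **Background**: temperature is a sinusoidal annual cycle (mean 28 °C,
  half-range 7 °C, maximum mid-January for the southern hemisphere) plus
  Gaussian daily noise (σ = 2 °C); rain is a Bernoulli wet-day process
  (p = 0.30) with exponential intensities (mean 8 mm/day), giving realistic
  zero inflation; wind is Weibull with shape 2 (Rayleigh-like) and scale
  3.5 m/s.  Defaults are set once at tropical-summer-plausible values.
- **Event**: a deterministic additive bump — Gaussian in space (radius
  2.5°, centered at 20.5° S, 141° E on the default grid) and top-hat in
  time (9 days from 30 January 2019) — adding 60 mm/day of rain, removing
  10 °C, and adding 6 m/s of wind at the center.  Because the bump is
  deterministic, differencing an event run against the background-only run
  with the same seed recovers it exactly, and onset/offset dates are sharp.
- **Ensembles**: member = skill·truth + (1 − skill)·background + Gaussian
  noise, clipped at zero for non-negative variables; skill 1 with zero
  noise reproduces the truth, skill 0 collapses to a climatological
  forecast.  Hindcasts are event-free full-year background draws,
  exchangeable across members and years.
- **RMM trajectories**: amplitude(t)·(cos θ, sin θ) with θ integrated from a
  prescribed angular speed, so a zero-speed sub-window with amplitude > 1
  creates an active stall of exactly that length.
- **MSLP anomalies**: a Gaussian low whose depth scales with MJO amplitude
  on active phase-6/7 days, demeaned over the trajectory, plus white noise.

Each variable draws from its own RNG stream derived from the master seed by
fixed offsets, so changing one variable's parameters cannot perturb the
others, and all outputs are bit-reproducible for a fixed seed.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: no spatial or temporal autocorrelation beyond the
event footprint, no pressure–wind balance or advection, no rain–temperature
dependence, no model biases other than an optional constant/distributional
offset, and no real MJO–weather teleconnection (the MSLP coupling is
imposed).  Results on synthetic data validate the statistical machinery,
not meteorological skill.

## Problem sizes and verification choices

The default analysis grid is 11 × 17 cells at 0.5° covering the Gulf box
(137–145° E, 18–23° S) with a five-year daily record (2015–2019); the
climatological-reference check uses a 2 × 2 grid over 30 years; hindcast
structural checks use a single cell with the full 23-year × 11-member
layout.  These sizes make every statistic well-sampled while keeping a full
test run under a minute.  The event-recovery regression (≥ 80% of event days
flagged at the center, < 15% of background days) was calibrated once with
the default generator settings and is frozen; the background rate includes
the ~10% in-sample exceedance that the percentile definition itself
guarantees.

## Known limitations

- Percentile thresholds at 1.5°-scale model resolution would in practice be
  regridded to the verification grid; only same-grid comparison is
  implemented here.
- The comprehensive climate index (temperature–humidity–radiation–wind) is
  out of scope; the chill index is the only hazard model.
- Gulf-averaged run durations in the synthetic world depend on the event
  footprint radius relative to the box, so they are shorter than the
  event-center durations; the run-statistics machinery itself is verified
  on constructed masks with known answers.
- NetCDF output is NetCDF3 classic: no compression and no groups, chosen
  for maximal reader compatibility.
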