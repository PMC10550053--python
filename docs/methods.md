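# Methods

## The damage model

Hourly air temperature `T_t` is first smoothed with a two-sided moving
average and then shifted forward by a whole-day lag; the frost damage
index over a measurement interval is the accumulated deficit below a
base temperature,

    FDI(t_n; T_base) = Σ_{t in (t_{n-1}, t_n]} min(T_t − T_base, 0)   [°C·h],

and canopy-cover change over the interval is `ΔCC = s · FDI` with a
nonnegative, genotype-specific sensitivity `s` (CC fraction per °C·h).
The model assumes damage is linear in the accumulated deficit, that the
lag and smoothing are crop-level (not genotype-level) properties, and
that within the analysed early-season window negative ΔCC is caused by
frost rather than disease or senescence.

Conventions that the code relies on:

- **Half-open intervals.** The FDI of (t_{n-1}, t_n] includes the
  endpoint hour and excludes the start, so adjacent intervals never
  double-count and the index is exactly additive over interval unions.
- **Smoothing span.** `smooth_hours = w` means a centred average over
  `w + 1` samples (odd and symmetric for the even spans on the fitting
  grid); windows shrink at the series edges rather than dropping data.
  A span of 0 is the identity.
- **Lag.** `lag_days = L` advances every timestamp by `L` days: damage
  observed on day d is attributed to temperature on day d − L. Integer
  days only, matching the daily damage grid.
- **Units.** The FDI is reported in °C·h (hourly sampling); degree-day
  conventions elsewhere are often °C·d — divide by 24 to compare.
- **Gaps.** Missing hours inside a requested interval raise a coverage
  error naming the missing span. Gaps of up to 3 h can be linearly
  infilled, but only on explicit request; silent infill would bias the
  deficit sum.

## Daily interpolation and the regression pairs

Measurements arrive at irregular intervals (roughly weekly in the
field), so interval ΔCC values are not comparable across intervals of
different length. CC is therefore interpolated linearly to calendar
days and differenced; the daily differences within one measurement
interval are equal and telescope exactly back to the raw interval
difference. Only declines (negative ΔCC) enter the fit.

The FDI is defined *between measurement time points*, so the daily
regression pairs distribute each retained interval the same way on both
sides: a day in a declining interval contributes the pair
(ΔCC_interval / len, FDI_interval / len). This keeps the regression
slope `s` identical to the interval-level slope while weighting each
interval by its length, which is the point of the daily interpolation.
The alternative — pairing each day's own sub-interval FDI against the
interval-constant daily ΔCC — mismatches a concentrated index with a
smeared observation; in simulation it drives the fitted base temperature
toward 0 °C and the smoothing to the grid maximum, so it was rejected.

## Step-wise estimation

1. **Lag** on the integer grid 0–10 d. For each candidate, the base
   temperature is fitted by correlation maximisation and the sensitivity
   by the closed-form slope on pooled (genotype-unspecific) data, the
   profile records Pearson r and RMSE, and the nuisance values are
   discarded. The lag with the highest r wins (both optima are
   reported; ties go to the smaller lag). Correlation rather than error
   is the primary criterion because an error criterion is minimised by
   predicting zero everywhere.
2. **Smoothing span** on 0, 6, …, 54, 56 h with the lag fixed, same
   nuisance handling. The default selection is a **compromise rule**:
   the grid value nearest the midpoint of the correlation optimum and
   the RMSE optimum, ties to the smaller span (`max_r` and `min_rmse`
   are available as explicit rules).
3. **Base temperature** with lag and span fixed: a coarse 0.5 °C grid
   over [−25, 0] followed by bounded scalar refinement between the
   neighbouring grid points. The coarse grid is needed because the
   correlation objective is piecewise-flat wherever no new frost hours
   enter between candidates; on an exactly flat plateau the warmest
   maximiser is taken as the most parsimonious threshold. Candidates
   with fewer than two nonzero-FDI pairs or undefined correlation score
   −∞.
4. **Sensitivity**, globally and per genotype, as
   `s = Σ(FDI·ΔCC)/Σ(FDI²)` clipped at zero — a negative slope would
   predict growth from frost, and the clip makes that explicit. A
   genotype needs at least 5 negative daily observations and at least
   one nonzero FDI among them; otherwise it is reported as *not
   estimable* rather than near-zero, because sparse-stress seasons
   otherwise collapse estimates toward zero without saying so.

All searches are deterministic given the inputs. The fitted model is
exposed as a scikit-learn-style estimator (`FrostDamageIndexModel`) with
`fit`/`predict` and trailing-underscore attributes, so it composes with
sklearn tooling; the module-level functions wrap the same machinery.

## Synthetic seasons

`simulate_temperature` builds hourly values as seasonal trend (cosine
with its minimum near DAS 90) + diurnal cosine (default amplitude 4 °C,
warmest at 14:00) + AR(1) noise (coefficient 0.8, marginal sd 1.5 °C —
autocorrelated so that smoothing has a realistic effect). Cold spells
depress the trend trapezoidally (ramp–plateau–ramp, the multi-day
plateau of a winter blocking high) down to a stated floor; the diurnal
cycle and noise ride on top, so realized minima are lower than the
floor. The series starts 14 days before sowing so that every lag on the
search grid leaves the first measured days covered.

`simulate_cc` applies the damage model on the daily grid:
`CC(d) = clip(CC(d−1) + growth + s_g · FDI_daily(d) + ε, 0, 1)`, where
the FDI uses the true lagged and smoothed temperature and growth is
logistic scaled by the day's growing degree days above 0 °C — near zero
in deep winter, rising in spring. Because damage is applied daily,
daily measurement schedules make the analysis-side interpolation exact
and exact-recovery tests well-posed. Observation noise is added to the
sampled CC measurements (`meas_noise_sd`); a separate daily process
noise (`cc_noise_sd`) exists but is zero in all presets.

Presets (all with truth lag 3 d, span 18 h, T_base −9 °C and a 36-
genotype panel with sensitivities drawn uniformly in [5·10⁻⁴, 5·10⁻³]):

- `noiseless` — one season, daily measurements, zero noise and growth;
  the master round-trip recovers every parameter to numeric tolerance.
- `field_like` — the two-season fitting panel the procedure is designed
  for: 36 genotypes × 7 rows per winter, irregular 5–9 day measurement
  intervals, thermal-time growth (0.004 per GDD), observation noise at
  10% of the mean absolute measured ΔCC. One winter carries its severe
  multi-day spell late (~DAS 131) and the other early (~DAS 120), each
  with four frost events: two short deep snaps (trend floor −10.2 °C),
  a weak spell (−7.8 °C) and the severe plateau (−8.7 °C). The mix is
  deliberate: the plateau events put many hours near the threshold and
  identify the base temperature and smoothing span, the weak events
  provide a second severity level, and the concentrated snaps anchor
  the lag. A single season is not enough — every row shares the same
  measurement dates, so lag information reduces to a handful of
  interval boundaries and the lag profile plateaus into near-ties.
- `sparse_stress` — one season with a single mild spell whose damage
  stays below daily growth, so declines rarely surface in ΔCC; most
  genotypes come out not estimable or near zero, reproducing the
  behaviour of seasons with little frost pressure.

What passing recovery tests on these data does *not* show: real CC
series carry segmentation errors, alignment drift, disease- and
senescence-driven declines, and damage that emerges gradually over
several days rather than on the generator's daily grid; none of these
are simulated, so field estimates will be noisier than the synthetic
recoveries suggest. Spell intensities are sized so that CC stays inside
[0.05, 0.95] for essentially all genotypes (rare extreme-seed
excursions clip at 0, slightly biasing the most sensitive genotype's
`s` in those runs).

## Row imaging

The plot de-rotation scores every angle on a 0.2° grid spanning ±1.5°
(zero-centred, so a straight plot scores a 0.0 correction) by the
max–min contrast of the window-100 sliding-mean-filtered column profile
of the rotated mask. The scoring rotates the plant-pixel coordinates
and bins them per column — the same nearest-pixel binning as rotating
the full image, without the warp; the de-rotation itself uses
nearest-neighbour resampling so the mask stays binary.

The 9-row sinus fit initialises its period from the autocorrelation
peak of the mean-subtracted column profile and co-estimates the plot
extent by thresholding the smoothed profile at 10% above the soil
floor; fitting across the soil margins instead biases the period
upward and fans the outer row centres out by several pixels. Offset,
amplitude and phase are free; the period is bounded to ±10% of its
initial value. Row centres are the sinus maxima inside the extent; when
more than nine fall inside, the nine consecutive maxima with the
highest profile support are kept. Each row's band spans its centre
± period/2, so the nine bands tile the plot, and CC is the plant-pixel
ratio in the band; the inner seven rows are reported.

Synthetic plot masks render each row as a solid vertical strip of width
cover × period (so band CC equals the nominal cover exactly), add soil
margins of half a period, optionally skew the mask and flip a stated
fraction of pixels to a fair coin. Rotation-recovery fixtures use
covers 0.55–0.68 and 2000-pixel-tall masks: the contrast criterion
resolves a single 0.2° step only when the widest strip is comparable to
the 100-column window and the vertical shear per step is a few pixels,
which also holds at the real acquisition scale (0.3 mm/px, ~400 px row
spacing, metre-scale plots).

## Numerical notes

- Pearson correlations are computed with `numpy.corrcoef`; zero-variance
  inputs are flagged (`pearson_r = None`) rather than propagated as NaN.
- The base-temperature refinement uses bounded Brent with `xatol` 1e-3;
  infeasible objective values are mapped to a large finite penalty.
- The sinus fit is a linear least-squares initialisation (offset +
  sin + cos on a small period grid) polished by one bounded
  `curve_fit`; an amplitude indistinguishable from zero raises a
  row-detection error instead of returning arbitrary phases.
- Profile grid searches skip candidates whose nuisance fit is
  infeasible (recorded as NaN) and fail only when every candidate is.
- Seeded `numpy.random.Generator`s drive all randomness; simulated
  datasets and rendered masks are bit-identical under a repeated seed.

## Limitations

- The linear damage model has no hardening/de-hardening physiology, no
  snow cover and no soil temperature; the base temperature is a single
  effective threshold.
- The lag is integer days and shared across genotypes; sub-daily or
  genotype-specific lags are not representable.
- Identification of lag and smoothing from field-like data depends on
  the number and diversity of frost events; a single event leaves the
  smoothing span nearly unidentified (the nuisance threshold absorbs
  it) and the reported grid profiles should be inspected before trusting
  the selections.
- The row extractor assumes exactly nine rows, near-vertical at ±1.5°,
  and pre-aligned masks; it does not segment plants or register image
  time series.
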