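# Methods

This note documents the models, parameter choices and numerical decisions
behind `driftdive`, and what the synthetic experiments do and do not show
about real dive records.

## The data model

A satellite-relay data logger samples depth at 2 s, abstracts each dive on
board with a broken-stick algorithm to four at-depth inflection points plus
the two surface points, and transmits the result. `driftdive` works with
both representations: `HiResDiveRecord` (regular samples, depth in metres
positive down) and `AbstractedDiveProfile` (six knots; the surface points
implicit at (0 s, 0 m) and (duration, 0 m)). Abstracted tables come in a
`seconds` dialect and a `percent` dialect in which inflection times are
percentages of dive duration (the logger transmission convention);
`t_i[s] = t_i[%] / 100 × duration`.

Vertical speed is `(depth_start − depth_end) / Δt` with depth positive
down, so passive sinking is negative. This makes the criteria bounds
(−0.6, −0.05 m s⁻¹, "next ≥ +0.2", "previous ≤ −0.6") literal. Local time
is solar mean time, `UTC + longitude/15 h`, with no civil zones or DST.

## Step-wise filtering

The seven criteria and their defaults live in `FilterConfig`. Boundary
handling: every numeric bound is inclusive except the minimum length
(strict `>`, "longer than 8 min") and the afternoon exclusion window,
which is half-open `[13:30, 19:30)` and may wrap midnight in other
configurations. Criteria are conjunctive, so the retained set is invariant
under the order of application (property-tested over random permutations);
the order only affects the step-wise attrition bookkeeping in
`FilterReport`. Single-criterion retention is reported against two
denominators — candidate fragments (indices 2–4 surviving preparation) and
all fragments — because either convention is defensible.

The fragment's clock time for the diel criterion is its start time by
default (`lt_anchor="start"`); a midpoint anchor is available since the
choice is not forced by anything in the data.

`allow_positive=False` removes positive vertical speeds a priori: adult
seals on these migrations are not expected to reach positive buoyancy.
For post-weaning pups or late-gestation females, set `allow_positive=True`
and widen `speed_max`.

## Broken-stick abstraction

Points are added greedily: starting from the surface endpoints, the sample
with the largest absolute *vertical* residual against the current polyline
is added, earliest sample winning ties, until four at-depth points are
chosen. Residuals are vertical depth differences, not perpendicular
distances — the standard iterative end-point fit for time series. Any dive
that is piecewise linear with at most four interior breakpoints is
reproduced exactly (tested against a brute-force per-iteration oracle).

Limitation: greedy refinement does **not** guarantee that the maximum
residual is monotone in the point budget for arbitrary profiles — adding a
knot can raise the residual of an opposite-signed neighbouring deviation.
On drift-dive geometry (one-sided deviations from the running chords) the
monotonicity holds and is tested there. The firmware's exact residual
metric and tie-break are not public; the tests therefore rely on
self-consistency (simulate → abstract → filter), not firmware equivalence.

## The simulator

No generative model of elephant-seal diving is implied by the biology; all
simulator distributions are artifact choices, made once, with the
following rationale:

* **Buoyancy trajectory**: logistic,
  `v(t) = v0 + (v1 − v0)·expit((t − t_mid)/scale)`, defaults
  `v0 = −0.35`, `v1 = −0.02 m s⁻¹`, `t_mid = 75 d`, `scale = 15 d` —
  strongly negative at departure, approaching neutral buoyancy around
  day 75–150, the pattern these records show. Per-dive realised drift rate
  is `v(day) + N(0, drift_noise_sd)` with `drift_noise_sd = 0.03 m s⁻¹`.
* **Dive mix** (`type_mix`): drift 4 %, V 46 %, U 40 %, D 10 %. Drift
  diving is a small fraction of a record; D-type dives are the deliberate
  confounder (below).
* **Drift-dive geometry**: descent at 1.4 m s⁻¹ to a start depth drawn in
  120–430 m (capped so the drift ends above 525 m), a drift phase of
  9–14 min, then a three-stage ascent at 0.8/1.1/1.4 m s⁻¹. The three
  ascent stages give the dive exactly four interior corners, so the
  broken-stick abstraction recovers the drift fragment exactly, and the
  first ascent stage (+0.8) and the descent (−1.4) satisfy the
  neighbouring-fragment criteria with margin.
* **D-type dives**: two slow glide-down limbs (rates −0.55 to −0.06
  m s⁻¹, i.e. inside the drift band) separated by a quick upward recovery
  stroke. The four bottom corners exhaust the abstraction's point budget
  and the first limb can pass every criterion — reproducing the known
  false-positive mode in which the abstracted bottom phase of an
  oscillating dive is indistinguishable from a drift. Limb durations and
  depths are spread so that a minority of D dives pass, which places the
  simulated confirmation percentage in the low-to-high 60s — the magnitude
  reported when this method is checked against visual classification.
* **Stroke noise**: active (swimming) segments carry a tapered sinusoidal
  depth wiggle (amplitude 2.5–4 m, period 55–75 s, 30 s ramps at segment
  ends so corner depths stay exact). Its purpose is to give the
  high-resolution record realistic vertical-speed variance outside drift
  phases; drift phases carry only sensor quantization (0.5 m by default).
  The period range deliberately avoids the 40 s decimation interval of the
  verification detector, where a sinusoid would alias to zero variance.
* **Diel structure**: 60 % of drift-dive start times fall in 02:00–07:00
  local time, the rest uniform — a morning peak in drift-fragment
  occurrence. Surface intervals are exponential (mean 2 min).

`detectable` labels drift dives whose planted phase satisfies all seven
criteria **with a safety margin** (0.02 m s⁻¹ on the speed band, 5 m on
depth, 60 s on the duration, 2 percentage points on the percentage, 10 min
on the time window), so that sample-grid snapping and quantization cannot
push a labelled dive across a boundary. Drift dives inside the margin band
keep their type but are not flagged detectable; recall statements refer to
the detectable set.

What passing tests show: the pipeline recovers exactly what was planted,
under the stated geometry and noise. What they do not show: performance on
real records with irregular drift phases, multiple drifts per dive,
transmission gaps, or the "second behaviour" clusters of slow vertical
speeds that only acceleration data can separate from true drifts.

## Minimum-length derivation

Candidate fragments are subsampled at length thresholds 1–15 min
(`duration > x`); for each subsample a generalized-cross-validated cubic
smoothing spline of vertical speed against time is fitted
(`scipy.interpolate.make_smoothing_spline`; duplicate time stamps are
averaged before fitting) and `R² = 1 − RSS/TSS` is computed on the raw
points. Cells with fewer than 10 fragments are missing. In field practice the
inflection of the R² curve is read off a boxplot by eye; the algorithmic
stand-in here takes the median curve across individuals and
returns the smallest threshold at the first local maximum of its first
differences exceeding `min_improvement = 0.05` — the largest single-step
improvement of fit. Monotone or flat curves return no recommendation with
a warning, and the full diagnostic curve is always returned for
inspection. `count_by_length` provides the companion diagnostic: the
duration histogram of fragments surviving the other six criteria.

## Quantile B-spline trends

The drift-rate trend is an unconstrained quantile B-spline in the COBS
style: quadratic B-spline coefficients minimise the check loss
`Σ ρ_τ(yᵢ − s(tᵢ))`, solved exactly as a linear program (HiGHS). Knots sit
at equally spaced empirical quantiles of the observation times; the knot
count (3–14) is selected by a Schwarz-type criterion on the check loss,
`n·log(loss/n) + ½·p·log n` — a simpler, deterministic search over the
same space as stepwise knot deletion, with the 14-knot cap preventing
over-fitting while leaving week-scale changes visible. No shape constraint
or roughness penalty is used. The conventional setting "quantile level
20 %" is read as the regression quantile τ = 0.2 (the fitted curve tracks the
lower envelope of the drift-rate cloud, which is conservative against
slow-speed contamination from above); users who read it as a
knot-placement setting can simply pass τ = 0.5. Splines are fitted
separately on either side of haul-out gaps (> 2 days by default; an
explicit haul-out flag can gate the split). Representative daily values
are the spline at local noon of each day inside the fitted domain — never
extrapolated. Confidence bands are out of scope: no construction method is
specified for them.

## High-resolution verification detector

The 2 s record is decimated to 40 s (strict decimation, keeping every
k-th sample); vertical speeds are consecutive depth differences. An 8 min
window slides one sample at a time over stretches where *all* samples are
deeper than 50 m (a mean-depth gate is available); windows with
`|mean v| < 1 m s⁻¹` and `sd(v) < 0.05 m s⁻¹` are flagged, and
overlapping or touching flagged windows merge into maximal segments, each
reporting its mean vertical speed. No post-smoothing is applied. The sd
threshold is per-individual tunable (0.05–0.1 covers noisier animals).

## Time-series comparison

Both drift-rate series are reduced to daily means (days without
observations stay absent). For ARIMA fitting, gaps of ≤ 3 days are
linearly interpolated and longer gaps split the series; correlation is
computed on common observed days without interpolation. The differencing
order d comes from repeated KPSS level-stationarity tests (α = 0.05, max
d = 2); (p, q) ≤ (5, 5) by corrected-AIC grid search at that d, maximum
likelihood throughout (statsmodels). The observed Pearson correlation of
the d-differenced pair is referred to an empirical null: N = 1000
index-paired pulls of one simulated series from each fitted model,
differenced by its own d, with the +1-corrected upper-tail p
`(1 + #{r ≥ r_obs})/(N + 1)` (positive correlation being the hypothesis;
a two-sided variant is available). Under independence this p is uniform;
the calibration is property-tested by Kolmogorov–Smirnov.

The power experiment mirrors the real verification design: filtered and
visually confirmed series measure the *same dives*, so they share the
latent daily drift rate — modelled as the logistic trajectory plus an
AR(1) day-to-day fluctuation (sd 0.05 m s⁻¹, φ = 0.7) — and differ only
by independent measurement noise (sd 0.015 m s⁻¹). A purely smooth shared
trend with independent daily noise would carry almost no signal into the
differenced series; the shared daily fluctuation is what the correlation
actually detects.

Count comparisons between migrations use the two-cell Pearson
goodness-of-fit statistic against equal expectation, no continuity
correction, df = 1, upper-tail p. Verification against labels is
per-dive: a selected dive is confirmed iff its label is drift-type;
unselected drift dives count as missed (the neutral terms `n_missed` /
`n_false_positive` are used throughout).

## Problem sizes and numerical notes

Simulated experiments use 100–200-day deployments at 40 dives/day for
filtering and trend recovery, 50 dives for the high-resolution detector,
3 × 400 fragments for the minimum-length derivation, and 100–200
replicates for the null-calibration and power checks — sizes at which the
sampling error of every reported statistic is small relative to its
acceptance tolerance. All randomness flows through
`numpy.random.default_rng` seeds; identical seeds give byte-identical
outputs. LP fits are exact to solver tolerance (≤ 1e−6 m s⁻¹ on
noiseless data); tie-breaks (earliest sample in abstraction, smallest
threshold in the inflection search, ±1e−9 float guards) are deterministic.
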