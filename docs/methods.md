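# Methods

## Data model and units

Inputs are per-singer tables: note events (onset, duration) and acoustic
localizations (time, position). Times are UTC epoch seconds internally,
ISO-8601 or epoch seconds in files. Positions are WGS84 decimal degrees;
`AnalysisConfig.coordinate_system = "planar"` reads the lat/lon slots as y/x
kilometres for synthetic scenarios. Every threshold lives in
`AnalysisConfig`; nothing is hard-coded:

| parameter | default | meaning |
|---|---|---|
| `min_notes` | 3 | minimum regularly spaced notes per song |
| `ini_min_s`, `ini_max_s` | 9, 20 s | typical inter-note band (diagnostic only) |
| `note_break_s` | 30 s | start-to-start interval that ends a song |
| `duty_window_min` | 30 min | trailing window for the segment duty-cycle |
| `robust_threshold_pct` | 70 % | robust vs intermittent singing |
| `speed_split_kmh` | 7 km/h | slow vs fast regime |
| `default_bec_min` | 35 min | fallback bout-ending criterion |
| `min_locations`, `min_track_duration_h` | 3, 1 h | track inclusion filter |
| `bec_bin_width_min` | 1 min | interval histogram bin width |

## Song assembly

Songs are assembled by one rule: successive notes whose start-to-start
interval exceeds `note_break_s` are split apart; maximal runs with at least
`min_notes` notes become songs. The inter-note-interval convention is
start-to-start because note durations (~1 s) are small against the 9–20 s
spacing and onsets are the robustly detected quantity. Intervals in
(20 s, 30 s] keep a song growing — the 9–20 s band is typical, not a rule —
and an interval of exactly 30 s continues the song (only "greater than"
breaks). The 9–20 s band is reported per song as a regularity fraction,
a diagnostic of fragmented singing, never an exclusion.

## Bout-ending criterion

Inter-song-intervals pooled across singers mix short within-bout rests with
long between-bout gaps. Their histogram (1 min bins, empty bins dropped, no
pseudocounts) is fit in log10 space with a biexponential
`y(t) = a_f e^{−λ_f t} + a_s e^{−λ_s t}` by nonlinear least squares:

* **Weighting.** Residuals carry weight √count — the delta-method inverse
  standard deviation of log10 of a Poisson count. Unweighted log-space
  fitting lets the many one-count bins in the far tail (survivors of the
  empty-bin drop) flatten the slow component; in simulation this biases the
  recovered rates by 20–50 %, while the weighted fit recovers the fast rate
  to ~1 % and the crossing to ~2 %. The extreme tail holding the last 1 % of
  counts is excluded for the same reason.
* **Initialization and restarts.** λ_f from the head slope of the log
  histogram, λ_s from the tail slope, amplitudes by back-projection to t = 0;
  ten jittered restarts (the loss surface is multimodal), best residual kept.
  Parameters are log-transformed so amplitudes and rates stay positive; the
  labels are assigned post hoc so λ_f > λ_s, flooring a rate that underflows
  at 1e-10 per minute.
* **"No biexponential structure."** The fit is rejected (and the pipeline
  falls back to `default_bec_min` with a warning) when the rate ratio
  λ_f/λ_s < 3 (the crossing time is numerically unstable as the rates
  converge), when the slow amplitude falls below one count, or when the
  second exponential fails to reduce the Poisson deviance of the binned
  counts by at least 18.4 (χ², 2 d.f., p = 1e-4) relative to a single
  exponential. On single-exponential samples of n = 10⁴ the deviance gain is
  single digits; on genuinely two-process samples it is in the thousands.

The criterion itself is the component crossing
`t* = ln(a_f/a_s)/(λ_f − λ_s)`: below t* an interval is more plausibly a
rest, above it a gap, and this threshold minimizes the expected misassigned
mass under the fitted model (verified against brute-force minimization in the
tests). The exact t* is kept on the fit; the pipeline uses the operational
value rounded to the nearest minute. An alternative reading in which the
amplitudes are mixture weights rather than count amplitudes shifts the
crossing to `ln(a_f λ_f / (a_s λ_s))/(λ_f − λ_s)`; this is surfaced in the
fit diagnostics (`bec_density_crossing`) but not used. Bouts split before any
song whose preceding interval is **≥** the criterion.

## Track kinematics

Segments connect successive localizations; distance is haversine on a sphere
of radius 6371 km (ellipsoidal refinement is pointless at 10–430 km scales
with >1 km localization noise). The duty-cycle window is the trailing 30 min
of the segment, clipped to the segment span for shorter segments (no singing
time is borrowed from the previous segment; `window_used` records the
clipping). Song overlap with the window is exact interval intersection —
rasterization exists only as a test oracle. Duty-cycle counts all silence,
including inter-bout gaps that fall inside a window: silence is silence
regardless of bout bookkeeping. The ≥ 10 km spacing of successive locations
is treated as a property of the data source (and of the simulator's
decimation), not a filter this package applies.

## Cohort statistics and additive models

Tracks are the unit of analysis: per-segment and per-song variables are first
reduced to per-track means (and minima/maxima), and all cohort statistics are
computed over those track values. The matched-pairs test compares, per singer
with at least one inter-bout interval, the time-weighted mean segment speed
inside bout spans against inter-bout spans; it is the classic paired *t*
(identical to the one-sample *t* on differences; zero-variance differences
are handled explicitly: identical vectors give t = 0, p = 1).

Skewed variables (sample skewness > 0.5) are transformed with the lognormal
Johnson SL transform `z = γ + δ ln(x − ξ)`. The shape parameters come from
percentile matching at the ±0.524 standard-normal points; the location ξ,
poorly determined by four quantiles alone, is refined by the classic
three-parameter-lognormal criterion of zeroing the skewness of `ln(x − ξ)`
(bounded below the sample minimum, floored at zero for nonnegative
quantities). On exact lognormal samples the transformed values pass a
normality test at α = 0.01 in ~100/100 seeds.

The additive models are penalized-spline GAMs (statsmodels `GLMGam`,
Gaussian, identity link): cubic B-splines (basis dimension 5) for swim speed,
number of songs and year, a cyclic cubic spline for day-of-year — the
seasonal singing peak straddles the year end, so the smooth must wrap —
centered for identifiability. Penalty weights are selected once on the full
model by AIC with a deterministic Nelder-Mead search (the library's default
stochastic search is not reproducible). Term significance uses the classic
approximate F-test for penalized terms — refit without the term, compare
residual sums of squares with degrees of freedom from the change in total
effective d.f. — because the library's per-term Wald test proved wildly
anti-conservative for pure-noise smooths (p ≈ 0 for predictors with no
effect). Backward elimination removes the largest-p term at α = 0.05 and
refits until all retained terms are significant. Partial effects are reported
centered, with ±1.96 s.e. bands, against the untransformed predictor.

**Monotonicity check.** "The speed effect is monotone decreasing" is
operationalized as a finite-difference sign test on the fitted curve sampled
at nine evenly spaced quantiles of the predictor between the 15th and 85th
percentiles, allowing any single rise smaller than 0.25 of the local
pointwise standard error. The interior range excludes the spline's boundary
flare (one-sided data support); the noise floor keeps sub-uncertainty
wiggles in flat regions from counting as trend reversals, while composition
bumps several times larger than the band still fail.

## Synthetic singer cohorts

The simulator generates the statistical structure the analysis assumes, with
every coefficient in `BehaviorParams`:

* **Two semi-Markov states.** `slow_singing` (lognormal speeds, median
  5 km/h; exponential dwells, mean 4 h, min 1 h) and `fast_transit`
  (median 12 km/h; dwells 40 min + Exp(1 h), so silent fast dwells are
  automatically valid inter-bout gaps). 31 % of singers never leave the slow
  state (their slow speeds are capped at 6.8 km/h — these are the
  slow-swimming singers by construction); of the rest, half go silent while
  fast and half sing fragmented songs. Mixed singers start slow with
  probability 0.38, making ~57 % of all singers start slow.
* **Singing micro-structure.** Within a singing span, per-song duty targets
  are `base − coef·speed + seasonal + noise` clipped to the state band
  (slow: 0.97 − 0.025·v in [0.70, 0.93]; fast: 0.32 − 0.02·v in [0, 0.35]).
  Rests are uniform 3–10 min (×2.5 in fast state); the song span is
  `d/(1−d)·rest` capped at 30 min, emitted as notes at uniform 9–20 s
  intervals; spans too short for three notes stay silent. A rest always
  carries across a state boundary so songs never merge across dwells.
  Seasonality is a cosine in day-of-year peaking December 1 (amplitude 0.04
  duty fraction); track dates are drawn around that peak (s.d. 55 days),
  years uniform 2003–2009.
* **Movement and observation.** Correlated random walk at 1 min steps
  (heading s.d. 0.08 rad/√min), decimated greedily to locations ≥ 10 km
  apart; track durations lognormal (median 9.5 h, σ = 0.8, clipped to
  1.5–70 h). Planar kilometres are mapped to latitude/longitude through a
  local tangent plane. The TDOA model adds range/c plus Gaussian noise to
  emission times and localizes by least squares over (x, y, emission time),
  flagging collinear-array geometry as low confidence.

At these defaults a 163-track cohort yields roughly 1 200–1 400
speed/duty-cycle segment pairs, a mean duty-cycle near 54 %, mean track
length near 86 km, an estimated bout criterion of 34–41 min, and duty-mode
fractions near 31 % (high) and 22 % (low).

**What the simulator does not emulate.** Localization error (positions are
decimated truth); the observed near-equality of singing and non-singing swim
speeds — here silent gaps occur in the fast state, so simulated singers are
systematically faster while silent and the paired test is strongly negative
rather than null; observed song durations (the duty targets and 3–10 min
rests jointly force slow-state songs of 15–30 min, longer than typically
reported, so the simulated cohort's mean song duration runs near 22 min);
and any acoustic propagation realism. Passing tests therefore demonstrate
that the pipeline recovers known structure of this generative family, not
that real data satisfy its assumptions.

## Problem sizes

The test suite and the acceptance script use: 100 two-exponential mixtures of
n = 5 000 intervals for BEC recovery; 1 000 random layouts for the duty-cycle
oracle; 1 000 coordinate pairs for the great-circle oracle; and ten seeded
163-track cohorts for the end-to-end sweep, with single-cohort fixtures of 30
tracks for unit tests. These sizes keep the full suite under two minutes on
one CPU while leaving the per-seed recovery probability near one.

## Known limitations

* The BEC estimator assumes two exponential-like processes; rest
  distributions far from exponential (e.g. strictly uniform) flatten the fast
  component and can shift the crossing by a few minutes.
* Backward elimination inherits the usual caveats of stepwise selection;
  retained-term p-values are conditional on the selected model.
* Segments within a track are not independent; as in the source analyses,
  inference is done on per-track means rather than with explicit
  autocorrelation models.
* The Wald-free term test is approximate: penalties are held fixed between
  the full and reduced fits rather than reselected.
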