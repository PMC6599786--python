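# finsong

Analysis of fin whale (*Balaenoptera physalus*) singing behavior against
swimming speed, for passive-acoustic datasets in which individual singers have
been detected, localized and tracked: streams of 20 Hz song notes plus
time-stamped positions per singer.

Male fin whales sing long sequences of short, intense "20 Hz" notes spaced
9–20 s apart. A **song** is a run of at least three regularly spaced notes
(inter-note intervals above 30 s break the run); songs are separated by 3–10
min rests within a **singing bout**, and bouts are separated by much longer
silences. The package implements the full analysis chain used to ask whether
whales that swim faster sing less:

1. **Song assembly** — greedy left-to-right grouping of each singer's note
   stream by the 30 s inter-note break rule; song duration runs from the start
   of the first note to the end of the last.
2. **Bout-ending criterion (BEC)** — the pooled inter-song-interval
   log-frequency distribution is fit with a four-parameter biexponential
   `y(t) = a_f e^{−λ_f t} + a_s e^{−λ_s t}`; the criterion is the component
   crossing `t* = ln(a_f/a_s)/(λ_f − λ_s)`, the interval length at which a
   silence becomes more likely to be a between-bout gap than a within-bout
   rest (this also minimizes expected misassignments). Song sequences are
   split into bouts at intervals ≥ the operational (rounded) BEC.
3. **Track kinematics** — per-segment swim speed from successive
   localizations (haversine, R = 6371 km, or planar for synthetic scenarios)
   and a **duty-cycle**: the percentage of the trailing 30 min of each
   segment spent singing. Duty-cycle ≥ 70% is "robust" singing; segment speed
   ≥ 7 km/h is the "fast" regime. Tracks need ≥ 3 locations and ≥ 1 h to
   enter the cohort.
4. **Cohort statistics and models** — tracks are the unit of analysis (each
   whale counted once): mean-of-track-means summaries, the speed × duty-cycle
   log₁₀ histogram with its bimodality (high 75–90% and low 0–5% duty modes),
   a matched-pairs *t*-test of singing vs non-singing swim speeds, the
   lognormal Johnson (SL) transform for skewed variables, and penalized-spline
   additive models (Gaussian, identity link) of mean duty-cycle and mean song
   duration against swim speed, number of songs, day-of-year (cyclic seasonal
   smooth) and year, with backward elimination at α = 0.05.
5. **Synthetic singer simulator** — semi-Markov two-state singers
   (slow/high-duty vs fast/low-duty-or-silent) moving by correlated random
   walk, with note-level song emission, 10 km location decimation and an
   optional hydrophone-array TDOA observation model, so the whole pipeline is
   testable without any restricted data.

## Worked example

```python
from finsong import generate_cohort, run_pipeline, AnalysisConfig

cohort = generate_cohort(n_tracks=163, seed=1)
result = run_pipeline(cohort.notes, cohort.locations, AnalysisConfig(rng_seed=1))

print(f"tracks included: {len(result.tracks)}")
print(f"BEC: {result.bec:.0f} min")
h = result.histogram
print(f"high-duty mode: {100*h.high_mode_fraction:.0f}%  "
      f"low-duty mode: {100*h.low_mode_fraction:.0f}%")
row = result.summary.table.loc["duty_cycle_pct"]
print(f"mean duty-cycle: {row['mean_of_means']:.1f}%")
speed = result.models["duty_cycle"].term("speed")
print(f"duty-cycle ~ s(speed): p = {speed.p_value:.2e}")
```

prints (exact values depend on the seed):

```
tracks included: 151
BEC: 40 min
high-duty mode: 32%  low-duty mode: 24%
mean duty-cycle: 53.0%
duty-cycle ~ s(speed): p = 2.07e-40
```

Of the 163 simulated singers, 151 pass the inclusion filter; the estimated
bout-ending criterion lands at the boundary between the simulator's 3–25 min
rests and its ≥ 40 min gaps; the duty-cycle distribution shows the two
behavioral modes; and the additive model recovers the generative decline of
singing effort with swimming speed at overwhelming significance.

The same pipeline runs from the shell:

```sh
finsong simulate --n-tracks 163 --seed 1 --out-dir out
finsong all --seed 1 --out-dir out        # simulate + full analysis
finsong stats --notes out/notes.csv --locations out/locations.csv --out-dir out
```

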