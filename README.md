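# actitrend

Longitudinal accelerometer processing and three-level mixed-model
estimation of age-related change in children's sedentary time and
physical activity.

Pooled, multi-study accelerometer repositories let epidemiologists ask
how daily movement behaviour changes as children grow: each
participant wears a hip-mounted ActiGraph for about a week at two or
three assessment waves spaced one to four years apart, and the
per-minute activity counts are reduced to daily minutes of sedentary
time (≤100 counts per minute, CPM), light-intensity activity (LPA,
101–2294 CPM) and moderate-to-vigorous activity (MVPA, ≥2295 CPM)
under a common processing protocol. `actitrend` implements that whole
pipeline as a tested, reusable package for researchers working with
such cohorts:

1. **Epoch processing** — read raw epoch CSVs, reintegrate to 60-s
   epochs, exclude the overnight window (23:00–06:00), detect
   non-wear as ≥60 min of consecutive zero counts with a 2-min
   interruption tolerance, and account daily wear time.
2. **Day/wave summaries** — Evenson cut-point intensity
   classification, the ≥600-min valid-day and
   ≥2-weekday + ≥1-weekend-day valid-file rules, and wear-time
   standardization: for each intensity I and wave w,
   `std_I(w) = raw_I(w) / wear(w) × pooled mean wear`, computed
   separately for all-days, weekday and weekend streams.
3. **Cohort derivation** — decimal age (days/365.25), the child vs
   adolescent dichotomy at baseline (<10 vs ≥10 y), season of
   measurement, LMS BMI z-scores with injectable reference cutoffs,
   inclusion rules (control arms only, ≥2 valid waves, first three
   waves), and baseline/follow-up change summaries.
4. **Modelling** — the annual change in each outcome is the age
   coefficient β of a sex- and season-adjusted linear mixed model with
   random intercepts for study and for participant within study
   (time points at level one),

   y₍tps₎ = β·age₍tps₎ + γ'x₍tps₎ + u₍s₎ + v₍ps₎ + ε₍tps₎,
   u₍s₎ ~ N(0, σ²_study), v₍ps₎ ~ N(0, σ²_participant),

   fit by REML with Wald 95% CIs, plus stratified fits and
   age-by-moderator interaction fits (day of week, sex, age group,
   weight group, maternal education, ethnicity).
5. **Simulation** — a seeded generator of synthetic multi-study
   cohorts (and optional epoch-level count traces with sleep,
   non-wear and intensity-graded counts) with every generating truth
   recorded, because the real pooled databases are access-controlled.

The modelling layer is scikit-learn-styled: `ThreeLevelMixedModel`
exposes `fit`, `get_params`/`set_params` and fitted `_` attributes and
can be cloned in sklearn tooling; `fit_three_level`, `fit_stratified`
and `fit_interaction` are thin functional wrappers.

## Worked example

```python
from actitrend import (SimConfig, simulate_cohort, fit_three_level,
                       ModelSpec, tidy_report)

cfg = SimConfig()                      # 5 studies x 100 participants, 2-3 waves
table, truth = simulate_cohort(cfg, seed=42)
res = fit_three_level(table, ModelSpec(outcome="sed"))
print(tidy_report({"sed:all": res})[["model", "term", "formatted"]])
```

prints

```
  model           term           formatted
sed:all      Intercept 102.1 (77.1, 127.1)
sed:all    sex[female]    14.4 (6.4, 22.3)
sed:all season[autumn]     1.7 (-4.4, 7.8)
sed:all season[summer] -12.8 (-18.8, -6.8)
sed:all season[winter]    10.1 (4.1, 16.2)
sed:all            age   24.5 (23.6, 25.4)
```

The `age` row is the estimate of interest: sedentary time rising
24.5 min/day per year of age (95% CI 23.6–25.4), recovering the
generating truth of +24.9 used by the default configuration within its
Wald interval on this single replicate. The intercept is the expected
sedentary minutes at age 0 for a boy in spring (an extrapolation —
ages span ~4–20 y); the sex and season rows are level shifts, not
slopes. Variance components for this fit are σ²_study ≈ 594,
σ²_participant ≈ 1547, σ²_residual ≈ 985 min², from 1224 observations
on 500 participants in 5 studies.

A full shell pipeline is also available:

```bash
actitrend simulate --out-dir sim/ --seed 42 --traces
actitrend process --epoch-dir sim/traces --out flagged.csv
actitrend summarize --flagged-epochs flagged.csv --out-days days.csv --out-waves waves.csv
actitrend model --data sim/analysis_table.csv --outcome sed --out coefs.csv
```

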