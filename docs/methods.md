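# Methods

## Processing model

Raw ActiGraph epoch files (any epoch length dividing 60 s) are
reintegrated to 60-s epochs by summing counts in windows anchored at
the series start; a trailing partial window is dropped. Timestamp gaps
in input files are a hard error by default — silent zero-filling would
manufacture non-wear — with an explicit `on_gap="zero_fill"` opt-in.

Non-wear is defined as a maximal window that begins and ends on
zero-count epochs, spans ≥60 min, and whose non-zero interruptions are
within tolerance. The tolerance is applied **per interruption** by
default: each interruption may last at most 2 consecutive non-zero
minutes, with no cap on the interrupting count magnitude and no limit
on the number of interruptions per bout. This is the dominant
convention in hip-worn children's accelerometry processing, but
because some pipelines treat the 2 minutes as a per-bout total, both
semantics are exposed (`interruption_mode="per_interruption" |
"per_bout"`). Detection runs over all epochs, including overnight —
physical non-wear does not respect clock boundaries — and the
overnight exclusion (epoch start times in the half-open window
[23:00, 06:00)) is applied independently, so a bout may straddle the
boundary. Requiring `min_bout ≥ tolerance + 2` guards the degenerate
case of a "bout" that cannot contain zeros on both sides of an
interruption.

Wear time is the count of worn, non-excluded minutes per local
calendar date of epoch start; the daily maximum is therefore
17 h = 1020 min. Intensity classification uses the Evenson youth
cut-points on counts per 60-s epoch — sedentary ≤100, light 101–2294,
MVPA ≥2295 CPM — overridable via configuration. A valid day has
≥600 wear minutes; a valid wave file has ≥2 valid weekdays and
≥1 valid weekend day (Saturday/Sunday). Streams (all days, weekdays,
weekend days) inherit wave validity from the all-days rule; a stream
with zero valid days is omitted with a warning.

Wear-time standardization removes between-wave wear differences:
`std_I(w) = raw_I(w)/wear(w) × pooled_mean_wear`, where the pooled
mean is the day-weighted mean wear over the participant's valid days
of that stream across waves. Because the three intensities partition
worn minutes exactly at 60-s epochs, standardized sed+LPA+MVPA equals
the pooled mean wear identically (closure is asserted to 1e-9
relative). Standardization is computed per stream because the
standard's defining formula instantiates on within-stream wear; no
rounding is applied until reporting (1 d.p.).

## Covariates and inclusion

Decimal age uses elapsed days / 365.25 (leap-safe), resolved
preferentially as date of birth to the first accelerometer day, then
an investigator-provided age, then date of birth to a proxy date.
The child/adolescent dichotomy cuts baseline age at 10 years
(child < 10). Season is meteorological by month, with a six-month
shift for southern-hemisphere studies (configured per study). BMI
z-scores use the LMS transform, z = ((x/M)^L − 1)/(L·S) with the
log-form limit at L = 0 implemented via `expm1` for numerical
stability at small |L|; reference (L, M, S) rows and the weight
category cutoffs are injected by the caller because the standard
growth references are licensed external tables — tests ship a
synthetic cutoff fixture (−2 / +1.33 z). Maternal education and
ethnicity are ingested as already-harmonised binary labels. Inclusion
keeps control arms of intervention studies, truncates each participant
to the first three waves, then requires ≥2 valid waves; the operation
is idempotent. Change summaries take the first valid wave as baseline
and the last retained wave as follow-up; cohort descriptives report
mean (SD) for levels and absolute change and median (IQR) for
relative change.

## Statistical model

The annual change in each outcome (wear-standardized min/day) is the
age coefficient of a linear mixed model with fixed effects for
decimal age, sex and season (three dummies, spring reference) and
random intercepts for study and for participant within study; time
points are level one. Random intercepts only is the minimal structure
consistent with a three-level design; a participant-level random age
slope is available behind `random_slope=True` as a sensitivity
option. Estimation is REML via statsmodels `MixedLM` (study as the
grouping factor, a participant variance component); inference is Wald
(normal) on fixed effects, reported as β (95% CI) with p-values from
the Wald z statistic. Reference levels are male, spring, weekday,
child, under/normal weight, low-mid maternal education, white.
Rows with missing covariates are dropped listwise per model and
counted (`n_dropped`). Non-convergent or singular fits are returned
flagged (`converged_ = False`), never silently.

Stratified analyses refit the model independently per stratum level
(degenerate strata are skipped with a warning). Interaction analyses
add the moderator main effect and an age-by-moderator term; the age
row then carries the reference-level slope, and the non-reference
slope is the sum of the age and interaction coefficients
(`implied_moderator_slope`). The day-of-week moderator is fit on
stacked weekday + weekend rows per wave sharing the participant
random intercept — the only design that yields a within-wave day
contrast.

Numerical caveats verified by the test suite: at the zero-variance
boundary the REML fit collapses to OLS, but boundary variance
estimates are small positives rather than exact zeros, so equality
with the OLS oracle is asserted at 1e-4 relative on the exposure
slope and 1e-3 on the remaining terms at n = 900 participants; and
duplicating every row is exactly invariant only under OLS — REML
re-estimates variance components and shifts GLS weights slightly, so
slope stability is asserted well within one standard error.

## Synthetic data

The generator emulates a pooled multi-study children's cohort in two
tiers sharing one configuration and truth record: a cheap wave-level
analysis table for model experiments, and optional epoch-level 60-s
traces for end-to-end processing tests.

Wave-level tier: five studies × 100 participants by default, each
with 2 or 3 waves (equal probability). Baseline age is truncated
normal, mean 10.6 y, SD 2.1, clipped to the 4.1–15.8 y observation
range; the second wave follows after a gap of N(2.5, 1.4²) years and
the third at a cumulative N(4.3, 1.1²) years, each floored at 0.5 y
(so realized means sit slightly above nominal). Covariate prevalences
default to 44.5% male, 89.2% white, 26.9% low/mid maternal education;
BMI z is N(0.34, 1.1²). Outcomes follow
`intercept + slope·(age − 10) + sex effect + season effect + study
intercept + participant intercept + residual`, with defaults (min/day
at age 10 for a boy in spring): sedentary 350 (slope +24.9), LPA 390
(slope −22.4), MVPA 56 (slope −2.5), so the expected composition sums
to 796 min/day at every age. Random-effect SDs default to
(study, participant, residual) = (18, 40, 30) for sedentary,
(16, 35, 28) for LPA and (2, 7, 5) for MVPA — chosen so study-level
heterogeneity is modest relative to between-participant variation and
so expected values stay ≥3 SDs from the truncation bounds over the
observable age span (MVPA's SDs are small for exactly this reason:
its mean approaches ~28 min/day at the oldest observed ages).
Outcomes are truncated to [0, wear_target = 850] with truncation
events counted in the truth record; under the defaults no truncation
occurs. Optional age-slope modifiers: per-moderator interaction
deltas applied in the non-reference level, and a weekend-stream slope
delta for stacked-stream designs. The config validator rejects
compositions whose expectation exceeds the wear target anywhere in
the observable age span.

Trace tier: each analysis row can be rendered as one or more full
calendar days of 60-s counts — overnight zeros 23:00–06:00, injected
non-wear bouts (default one per day, 60–120 min, with a ≤2-min
non-zero interruption 30% of the time), and worn epochs carrying
exactly the row's integer minute targets with counts drawn uniformly
within each intensity's CPM interval (MVPA capped at 10,000 CPM for
realism; worn sedentary epochs draw ≥1 so injected zero bouts never
silently extend). Window minutes beyond the targets are rendered as
trailing zeros contiguous with a bout or the overnight block, so
re-processing recovers the rendered wear and intensity minutes
exactly — a round-trip identity the tests assert.

What the simulation does **not** emulate: diurnal activity rhythms,
autocorrelated count series, device noise, seasonal confounding with
age, missing days, or drop-out. Passing recovery tests therefore
demonstrates that the estimation machinery is unbiased and correctly
calibrated under the declared generating model, not that the pipeline
is robust to every real-data pathology.

## Recovery experiments and problem sizes

Because the pooled data are access-controlled, the headline check is
simulation recovery at the published estimates: 50 seeded replicates
of 5 studies × 100 participants are generated with the all-days
annual-change truths (+24.9 / −22.4 / −2.5 min/day/year), a +2.5
age-by-sex sedentary interaction (boys' slope 23.5), and a −3.0
weekend MVPA slope, and refit. The mean recovered estimate must land
within 3 Monte-Carlo SEs of its generating truth and nominal 95%
intervals must cover the truth in ≥90% of replicates. These problem
sizes keep a full recovery run at a few minutes on one CPU while
leaving Monte-Carlo error well below the quantities of interest
(MC SE ≈ 0.06 min/day/year for the all-days slopes, ≈ 0.12 for the
interaction, whose between-participant contrast is identified less
precisely).

## Known limitations

- Wald intervals can undercover variance-component-heavy designs with
  very few studies; with 5 studies the study-level variance is noisy,
  though fixed-effect coverage remains near nominal in the recovery
  experiments.
- The per-interruption non-wear semantics and the absence of an
  interrupting-magnitude cap are conventions, not certainties, of the
  emulated protocol; both are configurable.
- The LMS machinery is fully implemented but ships no real growth
  reference values; callers must supply them.
- `read_epoch_csv` parses a common ActiGraph header dialect and plain
  timestamp/counts CSVs; exotic vendor exports need caller-side
  conversion.
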