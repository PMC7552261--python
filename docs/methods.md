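# Methods

This note documents the statistical procedures implemented in
`pantsense`, the synthetic herd model used to exercise them, the
numerical and design choices made where several reasonable options
existed, and what the test suite does and does not demonstrate.

## 1. Minute-stream processing

**Alignment and exclusion.** Validation is restricted to observed
minutes: sensor records are left-joined onto observer records by
`(animal_id, minute)`, and any minute that is undefined — or absent — on
either side is excluded. A minute undefined on both sides counts once in
the total but is attributed to both sources, so the per-source counts
can exceed the union. Duplicated keys within one source are an error,
not a silent de-duplication.

**The fill rule.** The transformation scans the *original* sequence left
to right. A state A becomes "established" when two consecutive defined
minutes share it; thereafter every minute is rewritten to A until two
consecutive original minutes share a different defined state B, which
becomes established starting at the first minute of that pair. Three
cases the rule's verbal statement leaves open are resolved as follows:

* *Leading minutes* before the first pair are left unchanged (no state
  is established yet).
* A *trailing single minute* is rewritten to the established state: the
  terminating condition ("until the next two consecutive records of a
  differing state") never occurs, so the established state persists.
* *Undefined minutes* are opaque: never rewritten, never counted toward
  a pair, and they reset the established state — a fresh pair must form
  after them. This is the conservative reading; smoothing across an
  undefined gap would manufacture behaviour where the sensor explicitly
  declined to classify.

Because the scan reads originals and writes to a copy, filled values can
never establish or extend runs themselves, and the transformation is
idempotent. The implementation is vectorised (last-establishing-pair and
last-undefined indices via running maxima); an independently written
stateful scan serves as the oracle in the tests, with exhaustive
agreement over every 3-letter sequence up to length 12.

An exact consequence used by the test harness: concatenating sequences
with single undefined separators and filling once is equivalent to
filling each sequence independently, since undefined both resets the
established state and survives unchanged.

## 2. Thermal indices and heat events

THI follows the NRC dry-bulb/relative-humidity formula; HLI follows the
two-branch black-globe formulation. Choices:

* The printed branch pair (`BG>25`, `BG<25`) leaves BG = 25 °C
  uncovered; the hot branch applies at the boundary.
* Wind speed is taken in m/s (units are not stated with the formula).
* THI is monotone increasing in humidity only above 14.4 °C (where
  1.8 T = 26 flips the correction's sign); the monotonicity test grids
  therefore start at 15 °C.
* Daily summaries use sample SD (n − 1 denominator).
* Records without black-globe temperature yield a missing HLI; no
  back-estimation from dry-bulb and solar is attempted.

Heat events are maximal runs of at least `min_days` (default 3)
consecutive calendar days on which the daily maxima of *both* indices
reach the threshold (default 90, applied jointly as published, although
classical HLI alert thresholds are far lower). A calendar gap breaks a
run. The detector is verified against brute-force enumeration of all
boolean day patterns up to length 14.

## 3. Validation statistics

Panting is the positive class; every other defined state is non-panting.

* **Sensitivity / specificity / PPV** are the standard ratios × 100.
  Confidence intervals use the Wilson score method (the source tables
  give 95 % CIs without naming a method; Wilson behaves well at the
  extreme proportions that occur in per-PS strata), clamped to contain
  the point estimate under floating-point round-off. Per-PS sensitivity
  strata contain only the observed-positive minutes of that score;
  specificity and PPV are computed overall. The overall sensitivity
  pools all PS ≥ 1 minutes rather than averaging per-PS values.
* **Per-PS agreement** is reported twice: the empirical percentage, and
  the back-transformed population-level prediction of a binomial-logit
  mixed model with the panting score as a fixed factor and an animal
  random intercept. statsmodels has no frequentist binomial GLMM, so the
  model is fitted in-package by maximising the Gauss–Hermite-integrated
  marginal likelihood (25 nodes, L-BFGS-B with σ ≥ 0; cell-mean coding
  so each coefficient is one PS level's logit). Predictions are at a
  random effect of zero with delta-method standard errors. At σ = 0 the
  model collapses exactly to a logistic GLM, which the tests exploit as
  an oracle, alongside a simulation with designed per-PS agreement.
* **Duration concordance** works on per-animal totals over evaluated
  minutes (observed = PS ≥ 1 minutes). Pearson *r* carries a Fisher-z
  interval; the calibration line regresses sensor duration on observed
  duration (the scatter-plot orientation). Lin's CCC uses sample
  (n − 1) moments; the identity CCC = r × C_b is exact by construction
  and asserted to 1 × 10⁻¹². The CCC interval uses Lin's asymptotic
  z-transformation, rewritten in terms of C_b so the r → 0 limit stays
  finite; C_b, having no standard closed-form interval, gets a seeded
  nonparametric bootstrap (1000 resamples).
* **Cohen's κ** uses marginal-product chance agreement and is undefined
  (None) when both raters used a single identical category.

The fill variant applies the fill transformation to each complete
per-animal sensor stream *before* alignment and exclusion. Filling after
exclusion would create false adjacencies across removed minutes; the
alternative order remains available through the run configuration.

## 4. Variability analysis

The outcome is hourly panting minutes per animal, from full
60-minute-covered clock hours only; daily totals use complete 24-hour
days only, then average across days.

* **Group models** fit `panting ~ factor * hour` with an animal random
  intercept by REML (statsmodels MixedLM; the default gradient optimiser
  occasionally hits a singular information matrix on small balanced
  data, in which case Powell and conjugate-gradient fallbacks are
  tried). Reported are population predicted means per level × hour, the
  SED between levels within each hour from the fixed-effect covariance,
  and its across-hour average. If no optimiser converges, raw cell means
  are returned and flagged.
* **Within-group CV** is 100 · SD/mean (sample SD) of the per-animal
  average daily panting total, per genotype or coat level.
* **Decile contrasts** rank animals within group by average daily total;
  ceil(0.10 · n) animals at each extreme (ties broken by animal id, so
  selection is deterministic), with mean hourly profiles and a Welch
  t-test on the daily totals. Selection is within group, matching the
  published per-category figures.
* **Panting versus index**: herd-level panting per hour averages animals
  within the hour (animals-then-hours, the default reading of an
  ambiguous description). The class table uses 5-unit bins (50–54, …)
  with an average SED from the pooled within-class variance; a quadratic
  is fitted by OLS on the hourly points. The onset threshold scans
  integer index classes upward from the lowest observed class and
  reports the first whose mean exceeds the base significantly at
  α = 0.05, using t-tests on the pooled-variance SED (per-pair Welch
  tests were rejected: base classes with two points have essentially no
  power). No multiplicity correction is applied by default, matching the
  letter-display style of published class tables; Bonferroni is
  available via configuration.
* **Attribute screening** (sex, weight, docility) is a per-factor mixed
  model with a Wald chi-square on the factor's coefficients, emitted for
  completeness; the group analysis itself is fixed to genotype, coat and
  hour.

## 5. The synthetic herd

The generator exists so that every estimator above can be run against
known truth. It emulates a summer feedlot study: 100 animals of two
Bos indicus fraction classes (54 % / 46 %) and three coat colours,
observed for 5 days.

**Weather.** Piecewise-cosine diurnal temperature between a dawn minimum
(19 °C at 05:00) and an afternoon maximum (35 °C at 15:00), normal
day-to-day offsets (SD 3 °C), small 10-minute noise; relative humidity
linear in the diurnal phase, 85 % at dawn to 30 % at the maximum;
black-globe temperature adds a solar gain of up to 12 °C; lognormal wind
around 2 m/s; 144 records per day. The resulting hourly THI spans
roughly 60–85 across a 5-day block.

**Panting process.** Each animal's per-minute panting occupancy is

    p_i(t) = clip(λ_i · (b + s·(THI_t − θ)₊ + q·(THI_t − θ)₊²), 0, c)
             + 1[THI_t > θ + 4] · (g_i + k_i)

with base occupancy b = 0.083 (≈ 5 min/h), onset θ = 64, slope
s = 0.015, curvature q = 0.0004, ceiling c = 0.60, genotype shift
g = +3 min/h for the low-indicus class, coat shifts k = +3 / +1.5 / 0
min/h for dark/tan/white. Minute states follow a two-state Markov chain
whose stationary occupancy equals p and whose mean panting-bout length
is 5 min (geometric). True PS is 2 where occupancy exceeds 0.45, else 1.

Design rationale for this structure, all of which was forced by
mechanism analysis during construction:

* The frailty λ_i is a *designed population*, not an i.i.d. sample: a
  scaled-Beta quantile grid laid out within each genotype group and
  shuffled. At herd sizes of ~100, i.i.d. frailty confounds the genotype
  contrast with chance frailty imbalance (sampling error of a group mean
  of a CV-0.8 variable is of the same order as the designed 3 min/h
  gap).
* One spread parameter, shared by both groups, is calibrated against the
  noise-free design reference day so that the mean within-group CV of
  daily panting totals equals the designed 80 %. Sharing the parameter
  keeps the thermal-response distribution identical across genotypes;
  the calibration accounts for the occupancy ceiling and each group's
  additive-effect accrual. The one-sided group shifts make the two
  groups' realised CVs straddle the target (≈ 73 % / 84 %).
* Group effects are non-negative, additive, applied outside the frailty
  product, and gated at θ + 4: negative effects floor out at zero for
  low-frailty animals, effects inside the product are eaten by the
  ceiling, and gating at the onset itself lets the effects accrue over
  so many hours that they depress the CV of the heavier-panting group.
* The ceiling c = 0.60 keeps p below the chain's saturation point — a
  two-state chain with exit rate 1/5 cannot hold a stationary occupancy
  above 1/(1 + 1/5) ≈ 0.83, and propensities near that limit
  truncate the designed contrast. It also keeps top animals near the
  ~30–40 min/h that real top-decile panters show.

**Sensor corruption.** The designed minute-level miss rate (0.40) and
false-alarm rate (0.20) are injected as *isolated* single-minute flips:
within each behaviour run the first minute flips with probability q and
each later minute with probability q/(1−q) only if its predecessor did
not, which gives every minute an exact marginal flip probability q while
making adjacent within-run flips impossible. Unstructured independent
confusion and an undefined rate (default 1 %, matching the scale of
published tag-undefined counts) can be added on top.

**Observers.** Two observers focal-sample between 08:00 and 17:00, up to
15 min per animal, preferring currently panting animals 5:1, never
observing the same animal twice in one day (across both observers).
Windows end early with probability 0.05 per minute (last minute recorded
undefined) and individual minutes are undefined at 15 %, together
matching the ~20 % observer-undefined share of the published counts.
Observers record the true state and score; observer misclassification is
not modelled (published inter-observer κ was 0.91).

All randomness derives from one integer seed through named
`SeedSequence` child streams; a fixed seed reproduces every output table
byte for byte.

## 6. What the recovery tests show — and do not show

On the default scenario, the validation chain (focal-sampled observer
minutes against the corrupted sensor stream) recovers the designed
sensitivity and specificity to within a percentage point — the
estimators are unbiased for the error rates they target, at the minute
counts the protocol yields (~4 000 evaluated minutes).

The panting-process parameters (genotype gap, within-group CV, THI
onset) are recovered by the variability estimators applied to the true
behaviour streams: gap within ±0.5 min/h, CVs within ±10 points, onset
within ±2 THI units in well over 80 % of replicate herds. Run through
the *sensor* chain instead, the gap attenuates to ~0.7× and the detected
onset shifts upward by 2–4 units even after fill smoothing: with 5-min
mean bouts and a 40 % miss rate, the fill rule destroys short bouts
about as often as it repairs isolated errors. That attenuation is a
property of the measurement process, not of the estimators — it is the
same phenomenon that separates the published raw and fill sensitivities
— and it is why sensor-derived group contrasts should be read as
lower bounds. The CV, being a ratio, passes through the roughly
multiplicative sensor chain essentially unchanged.

The fill rule's benefit is demonstrated on a flip-only scenario with
10-min mean bouts (miss 0.30, false alarm 0.15, no undefined): raw
sensitivity ~70 % versus fill ~86 %. With the default 5-min bouts the
improvement is a few points only, consistent with the mechanism above.

What passing these tests does *not* show about real data: the generator
has no observer error, no clock drift between tag and tablet, no
spatial/microclimate structure, no behaviour classes beyond the binary
panting/other (so no confusion structure between panting and, say,
rumination), no day-on-feed or ration effects, Markovian bouts with a
single mean length, and weather without fronts or rain. Conclusions
about the statistical machinery transfer; conclusions about the sensor
itself do not.

## 7. Degenerate inputs and numerical conventions

Timestamps are timezone-naive local time at minute resolution; windows
are half-open `[start, end)`. Zero-denominator proportions are reported
as absent with a logged reason, not as zero. Concordance and correlation
require ≥ 3 pairs and positive variance on both axes. The quadratic
index fit refuses fewer than 3 occupied classes; the threshold scan
needs ≥ 2 usable integer classes (≥ 2 points each) and reports "none
found" (None) on flat series. Empty streams fill to empty streams.
CSV files are UTF-8 with ISO-8601 timestamps and decimal points.
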