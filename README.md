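# pantsense

Validation of accelerometer ear-tag **panting** detection for feedlot
cattle, and analysis of individual heat-stress variability against
thermal indices.

Panting score (PS, an ordinal 0–4.5 visual grade of respiratory
dynamics) is the standard animal-side indicator of heat load in cattle,
but continuous visual scoring does not scale. Commercial ear-tag
accelerometers emit a per-minute behaviour state (`panting` / `other` /
`undefined`) that can stand in for the observer — if the minute-level
classifications can be trusted. `pantsense` implements the complete
statistical machinery for that question, plus the downstream herd
analysis it enables:

* **Minute streams** — observer/sensor alignment on `(animal, minute)`,
  undefined-minute exclusion bookkeeping, run-length (bout) utilities,
  and the **fill** transformation: once two consecutive minutes share a
  state, any single differing minute is rewritten to the established
  state until two consecutive minutes of a different state occur.
  Isolated single-minute misclassifications inside sustained bouts are
  thereby repaired.
* **Thermal indices** — temperature–humidity index
  `THI = (1.8T + 32) − (0.55 − 0.0055·RH)(1.8T − 26)` and heat-load
  index `HLI = 8.62 + 0.38·RH + 1.55·BG − 0.5·WS + e^(2.4−WS)` for
  black-globe temperature BG ≥ 25 °C (a second branch below), hourly and
  daily summaries, and heat-event detection (≥ 3 consecutive days with
  daily maximum THI *and* HLI ≥ 90).
* **Validation statistics** — minute-by-minute sensitivity, specificity
  and positive predictive value with Wilson 95 % CIs (overall and per
  PS); empirical and model-predicted per-PS agreement from a
  binomial-logit mixed model (PS fixed, animal random intercept, fitted
  by Gauss–Hermite maximum likelihood); per-animal panting-duration
  concordance: Pearson *r* (Fisher-z CI), least-squares calibration
  line, and Lin's concordance correlation coefficient with its
  bias-correction factor, CCC = *r* × C_b; Cohen's κ for inter-observer
  reliability.
* **Variability analysis** — hourly panting minutes per animal; REML
  linear mixed models `y = µ + G + H + G·H + animal` (genotype × hour)
  and the coat-colour analogue, with predicted means and SEDs;
  within-group coefficients of variation; top/bottom-decile contrasts;
  herd panting across 5-unit THI/HLI classes with a quadratic fit and a
  panting-onset threshold scan.
* **Synthetic herd generator** — diurnal weather, a designed
  thermal-response panting process (animal frailty, genotype and coat
  effects, Markov bout structure), isolated-flip sensor corruption and a
  two-observer focal-sampling protocol, all seeded and byte-reproducible,
  so every estimator can be checked against known truth.

## Worked example

Simulate a 100-head herd over 5 summer days and run both analyses:

```bash
pantsense simulate --out demo            # writes weather/sensor/observer/attribute CSVs
pantsense run-all --indir demo --out demo/results
```

which prints (abridged):

```
raw: kept 4250/5303 minutes; sensitivity 59% (57-62)
fill: kept 4250/5303 minutes; sensitivity 62% (59-64)
genotype CV%: BI50=81, LT40_BI=73
coat CV%: dark=68, tan=85, white=98
panting onset: THI 68, HLI 55
```

Reading this: of 5 303 observer minutes, 1 053 were undefined on one
side or the other and excluded. The sensor in this scenario was designed
to miss 40 % of panting minutes (so raw sensitivity sits at ~60 %); the
fill rule recovers a few points because some errors are isolated inside
bouts. Panting varies enormously between animals of the same genotype
(CV ≥ 70 %), and herd-level panting (here measured through the
fill-smoothed sensor stream) rises significantly out of its base level
at a THI in the high 60s — below the classical heat-stress thresholds,
which is the study's practical message. Full reports
(`validation_report.json`, `variability_report.json`, per-group CSV
tables) land in `demo/results`.

The same flow is available as a library:

```python
from pantsense import HerdScenario, simulate_herd, run_experiment1, RunConfig

sim = simulate_herd(HerdScenario(seed=1))
reports = run_experiment1(sim.observations, sim.sensor_streams(), RunConfig())
print(reports["fill"].ccc.ccc)   # concordance of per-animal durations
```

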