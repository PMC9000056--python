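# timeuse-coda

Compositional data analysis of 24-hour time-use behaviors (sleep,
sedentary behavior, light and moderate-to-vigorous physical activity)
in adolescents, as a tested, reusable pipeline:

- **`timeuse_coda.accel`** — reduction of per-epoch accelerometer count
  streams to valid daily behavior minutes: 60-s reintegration, pluggable
  sleep scoring with consolidation of the main nocturnal period, non-wear
  detection (zero runs ≥ 20 min outside sleep), configurable intensity
  cut-points, wake/night validity rules and subject inclusion with reason
  codes.
- **`timeuse_coda.coda`** — Aitchison-geometry primitives: closure,
  sequential-binary-partition ilr transform and inverse, compositional
  center, classical and robust (MCD) variation matrix, total variance,
  robust Mahalanobis outlier detection in ilr coordinates.
- **`timeuse_coda.guidelines`** — guideline compliance (sleep 8–10 h,
  MVPA ≥ 60 min, screen time < 2 h), Venn-cell accounting, pooled
  two-proportion z-tests, rank-sum comparisons with rank-biserial effect
  sizes and bootstrap CIs.
- **`timeuse_coda.model`** — OLS of BMI z-score on the ilr coordinate
  block plus covariates, stepwise-AIC simplification with the
  compositional block protected, VIF diagnostics, sequential ANOVA,
  t-based coefficient CIs; all basis-invariant quantities are invariant
  to the SBP choice.
- **`timeuse_coda.isotemporal`** — model-based estimates of zBMI change
  for one-to-one time reallocations (15–120 min) between behaviors, with
  CIs, feasibility handling, selectable baseline modes
  (compositional center / arithmetic mean / per-subject), and asymmetry
  reporting.
- **`timeuse_coda.synthetic`** — logistic-normal cohorts with planted
  regression coefficients and recorded ground truth, plus synthetic
  count streams with injected sleep blocks and non-wear runs, so every
  stage is testable without external data.

## CLI

```sh
timeuse-coda simulate --n 185 --seed 1 --out results/cohort
timeuse-coda describe  --input results/cohort/cohort.csv --out results/describe
timeuse-coda comply    --input results/cohort/cohort.csv --out results/comply
timeuse-coda fit       --input results/cohort/cohort.csv --out results/fit
timeuse-coda reallocate --input results/cohort/cohort.csv --out results/realloc
timeuse-coda process   --streams streams/ --config accel.yaml --out results/accel
timeuse-coda run       --config pipeline.yaml --seed 1 --out results/run
```

`run` executes simulate/describe/comply/fit/reallocate end-to-end from a
YAML config (`n`, `seed`, or `input: path.csv|.xlsx` to analyze an
existing subject table). Every output directory gets a
`provenance.json` (package version, seed, config hash); fixed seeds give
byte-identical outputs.

Subject tables are CSV or XLSX with columns
`id, sex, age_years, ses_score, screen_hours, sleep_min, sb_min,
lpa_min, mvpa_min, zbmi`. An alias-tolerant loader
(`timeuse_coda.io.load_external_table`) handles externally deposited
spreadsheets with differing headers.

## Notes

- Scientific thresholds (intensity cut-points, sleep-scorer constants)
  are configuration. Defaults for the sleep scorer follow the published
  actigraphic algorithm; cut-points have **no** defaults and must be
  supplied.
- Robust estimation uses scikit-learn's FastMCD with a fixed
  `random_state` (reproducible); the scatter is estimated in ilr
  coordinates, making all robust outputs invariant to the SBP choice.
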