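# migenv

Toolkit for case-control and case-case analysis of long-term environmental
exposures against EHR-derived migraine outcomes, exercised end to end on
synthetic cohorts with known ground truth.

## What it does

- **`migenv.synthetic`** — generates the full study world: counties and
  block groups with smooth pollutant surfaces (PM2.5, NO2), point-source
  emitters (kg/hour rates) and well fields, and patient cohorts whose
  latent case status follows a logistic model with county random
  intercepts and configurable exposure effects. Cases carry EHR event
  streams (encounters, problem-list entries, medication fills) built to be
  exactly consistent with the scoring configuration, plus
  negative-binomial severity counts with person-year offsets.
- **`migenv.exposure`** — per-patient exposure assessment: block-group
  pollutant linkage and inverse-distance-squared aggregation of emitter
  emissions (`sum E_i / d_ij^2`) and active wells (`sum 1 / d_ij^2`)
  within a closed 10 km buffer (configurable radius, distance floor and
  geodesic/planar metric), with binary presence indicators and
  reporting-scale rescaling (per 5 µg/m³, per 5 ppb, per 100,000 kg/hour,
  per 1000 IDW units).
- **`migenv.ascertain`** — an EHR phenotyping score in [0, 101] built from
  three component classes (migraine-coded encounters, problem-list entry,
  abortive fills); score > 10 defines a case, > 100 the severe stratum.
  Weights are a configurable surrogate (YAML). Also builds the five
  severity outcomes (three per-person-year rates, any ED visit, severe
  score).
- **`migenv.matching`** — 3:1 frequency matching on age category, sex,
  entry year and follow-up category, with per-stratum shortfall reporting.
- **`migenv.glmm`** — random-intercept logistic and NB2 negative-binomial
  models fit by adaptive Gauss–Hermite quadrature (written from scratch;
  validated against dense numerical integration and, at `sigma_u = 0`,
  against independent GLM implementations). Wald CIs from the
  observed-information inverse; honest convergence flags.
- **`migenv.spline`** — penalized cubic B-spline (P-spline) nonlinearity
  check with Laplace-approximate marginal-likelihood smoothing selection,
  effective-df and monotonicity summaries.
- **`migenv.diagnostics`** — Moran's I on model deviance residuals with
  k-nearest-neighbour weights and a permutation null.
- **`migenv.pipeline`** — orchestration: scoring, matching, exposure
  linkage, the three-step exclusion cascade with exact per-arm accounting,
  the case-control grid (4 continuous + 2 binary exposures + spline
  checks), the case-case grid (6 exposures × 5 severity outcomes), three
  sensitivity analyses (emitter-category split, BMI/marital adjustment,
  distance-to-ED adjustment) and spatial diagnostics.

## CLI

```bash
migenv synth --n-counties 27 --n-block-groups 500 --n-patients 5000 \
    --seed 1 --out data/
migenv exposures --patients data/patients.csv --emitters data/emitters.csv \
    --wells data/wells.csv --block-groups data/block_groups.csv \
    --radius 10 --floor 0.05 --out exposures.csv
migenv ascertain --events data/events.csv --patients data/patients.csv --out asc/
migenv match --patients data/patients.csv --scores asc/mpa_scores.csv \
    --ratio 3 --seed 1 --out matched/
migenv run-all --config study.yaml --out results/
migenv diagnose --values residuals.csv --n-perm 999
```

`run-all` reads a single YAML study configuration (paths, buffer radius,
scoring weights, matching ratio/seed, covariate set, sensitivity toggles)
and writes delimited result tables: exclusion report, matching strata,
effect estimates with 95% CIs, spline summaries, and a Moran table, one
row per fitted model. With `--strict` the exit status is nonzero if any
model failed to converge.

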