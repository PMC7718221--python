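# reefcleaner

Mixed-model analysis pipeline for cleaner–client mutualism observation
data. The package covers the full analysis chain for long-term focal
observations at cleaning stations:

- **Synthetic data** (`reefcleaner.synth`): seeded generation of client
  communities, mapped cleaning stations, and observation/event tables
  whose counts and durations are drawn from the same model families the
  analysis fits (binomial-probit counts weighted by observation length,
  log-link Gaussian absolute-logit duration proportions), with
  station-level random intercepts and per-factor coefficient
  trajectories that are either constant across years, year-varying, or
  null. Also derives the 12 contextual factors (3 partner-identity, 4
  partner-abundance, 5 third-party) and Table-style per-year summaries.
- **GLMM core** (`reefcleaner.glmm`): random-intercept GLMMs fitted by
  penalized IRLS with profiled variance components (the fast
  no-quadrature mode of lme4, `agq0`; validated coefficient-for-
  coefficient against `glmer(..., nAGQ=0)`), plus a `laplace` mode,
  likelihood-ratio tests, Pearson overdispersion ratio, adjusted
  deviance pseudo-R², duration transforms, and Tukey (studentized-range)
  post-hoc contrasts. Nested grouping factors (events within
  observations within stations) are solved in O(q) via a diagonal Schur
  complement.
- **Model workflow** (`reefcleaner.workflow`): backward stepwise
  deletion with a forward-selection cross-check, VIF screening,
  added-last adjusted-R² importance (per predictor and per factor
  group), temporal models with time-of-day nested in year, per-year
  nested significance of retained predictors, and the observer-type
  sensitivity check.
- **Consistency classification** (`reefcleaner.consistency`): refits the
  final model on (by default) 1000 random subsamples of 192
  observations, labels predictors *consistent* (significant in ≥95% of
  refits), *dynamic* (significant on the full data but below the
  threshold), or *non-predictor*, ranks consistent predictors by the
  share of refits in which their |β| was largest, and reports empirical
  β intervals.
- **Spatial analysis** (`reefcleaner.spatial`): per-station predicted
  means with relative standard errors, Mantel permutation tests
  (including exact enumeration for tiny instances), aggregation PC1
  scores from nearest-neighbour distance and neighbour counts within
  3 m / 5 m, aggregation–behaviour correlations, and the
  station-random-effect LRT.
- **CLI** (`reefcleaner.cli` / `reefcleaner` console script) with
  subcommands `simulate`, `analyze`, `consistency`, `spatial`,
  `summarize`, all driven by a flat YAML config
  (`reefcleaner.config.RunConfig`), writing CSV outputs stamped with the
  config hash and master seed.

## CLI quick start

```sh
# generate a synthetic 8-year dataset (1536 observations)
reefcleaner simulate --out out/sim --seed 1

# full factor + consistency analysis (small n_sim for a quick look)
cat > cfg.yaml <<EOF
observations: out/sim/observations.csv
events: out/sim/events.csv
traits: out/sim/traits.csv
survey: out/sim/survey.csv
stations: out/sim/stations.csv
n_sim: 100
EOF
reefcleaner analyze --config cfg.yaml --out out/analysis --seed 1
reefcleaner spatial --config cfg.yaml --response clean_frequency --out out/sp
reefcleaner summarize --observations out/sim/observations.csv
```

Exit codes: 0 success, 1 validation error, 2 runtime error.

## Notes on conventions

- Continuous predictors are scaled and centred (sample sd) before
  fitting; standardization is frozen on the full dataset before
  subsample refits so β values are comparable across refits.
- Binomial trials default to `round(observed_minutes × k)` with k = 6
  opportunities per minute (configurable), realizing observation-length
  weighting as an explicit denominator.
- Duration responses are `|logit(p)|` with p clamped to
  [ε, 1−ε] (ε = 1e-4) and exact zeros floored at 1e-6 before log-link
  Gaussian fitting; duration models optionally weight by observation
  length (on by default).
- Random-effect LRTs are reported at df = 1 with no boundary
  correction. Non-converged fits are recorded outcomes, never
  mid-pipeline exceptions; non-converged subsample refits are excluded
  from both numerator and denominator of significance proportions.
- p-value range bars per predictor (as in a consistency figure) can be
  plotted from the exported per-run records on a logit-scaled axis;
  plotting itself is out of scope.
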