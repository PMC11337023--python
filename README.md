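# ensoyield

Distributed-lag non-linear modelling (DLNM) of climate-index (ENSO) impacts on
oil-palm yield panels, exercised end-to-end on a synthetic estate-month panel
generator with known ground-truth exposure-lag-response surfaces.

The package implements:

- **`ensoyield.synthetic`** — estate-month panel generator: AR(1)-plus-events
  monthly climate index shared by all estates, calendar seasonality (February
  trough, September–October peak), state/estate heterogeneity, state-specific
  quadratic weather teleconnections, and a configurable piecewise-quadratic
  exposure-lag-response surface (`TrueSurface`) with closed-form cumulative
  effects for recovery testing.
- **`ensoyield.preprocess`** — outcome construction (FFB yield = mass/area,
  oil yield = FFB yield × OER/100), strict exclusion filters (yield > 6
  t/ha/month, OER > 30 %), missing-category encoding (zero/missing fertilizer
  cost → reference level), quantile groupings, 24-month rolling averages,
  mm/day → mm/month conversion, per-state quadratic teleconnection fits,
  descriptive summaries.
- **`ensoyield.lagbasis`** — exposure histories, B-spline bases (boundary
  checked, no extrapolation), log-scale lag knots `L**(i/(nk+1))`, and the
  vectorized cross-basis (exposure basis ⊗ lag basis, lag-summed outer
  products).
- **`ensoyield.select`** — LASSO covariate screening by hand-rolled cyclic
  coordinate descent on a Gram matrix, with seeded k-fold cross-validation of
  the penalty path (minimum mean CV error rule).
- **`ensoyield.modelfit`** — OLS fit of cross-basis + selected covariates +
  calendar-month and state fixed effects, with pivoted-QR rank diagnostics,
  Gaussian AIC, AIC-based maximum-lag selection (ties → fewer lags), and a
  REML random-intercept robustness fit.
- **`ensoyield.association`** — cumulative and lag-specific contrasts versus
  the reference exposure (0) with delta-method CIs, contour surfaces,
  summary tables, per-month equivalents and percent-of-mean conversions.
- **`ensoyield.subgroup`** — stratified refits, two-sample z-tests of
  cumulative effects, and group-count-dependent significance thresholds
  (0.05, 0.025, 0.0125 for 2/3/5 groups).
- **`ensoyield.cli`** — pipeline orchestration.

## CLI

```sh
ensoyield -c config.yaml simulate     # synthetic panel + index CSV only
ensoyield -c config.yaml all          # full pipeline -> curve/table/surface/
                                      # subgroup CSVs, fit bundles, manifest
```

Example `config.yaml`:

```yaml
out_dir: run1
outcomes: [ffb_yield, oer, oil_yield]
lag_candidates: [10, 23]
seed: 7
sim:
  n_estates: 200
  seed: 7
```

Every output CSV embeds the config hash; identical config + seed reproduces
byte-identical outputs.

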