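# Methods

## Setting and estimand

Units are children aged 2–17 sampled by a weighted survey. The outcome `Y`
(systolic blood pressure, mm Hg) is observed (`R = 1`) only for some
children aged 8–17 and for none aged 2–7. The estimand is the weighted
population mean `mu = E[Y]`. Within ages 8–17 we assume missingness is
at random given age (conditional exchangeability), and positivity holds:
every age 8–17 has a nonzero probability of an observed outcome. Below age
8 positivity is violated *by design* — the probability of observation is
exactly zero — so no statistical adjustment, however flexible, can identify
`E[Y | age < 8]` from the sample alone.

## The synthesis estimator

Decomposing on the positivity-region indicator `X*`:

    mu = e1·p1 + e0·p0,  e1 = E[Y | X*=1], e0 = E[Y | X*=0], p1 = Pr(X*=1)

- `p1, p0`: survey-weighted shares; they always sum to one exactly.
- `e1`: g-computation with a saturated age model fit by weighted least
  squares to complete cases aged 8–17. Because the model is saturated, each
  coefficient is identically the survey-weighted complete-case mean at that
  age, and the implementation uses that closed form (a statsmodels WLS fit
  on age indicators is the cross-check in the test suite). Predictions are
  averaged, with the survey weights, over *all* positive-region units.
- `e0`: the mathematical model. Each never-observed child is matched to an
  external table cell by (age, gender, height percentile) and imputed by a
  draw from `Normal(P50, (P90 − P50)/z)` with `z = Φ⁻¹(0.90)` computed at
  runtime to full double precision (≈ 1.2815516). A degenerate cell
  (`P90 = P50`) is a point mass. The survey-weighted mean of the
  imputations estimates `e0`. Validity rests on the untestable assumption
  that the external source and the target population agree on all other
  SBP predictors.

Comparison estimators: the complete-case weighted mean (biased upward here,
since the never-observed children are the youngest and SBP rises with age)
and linear extrapolation (a weighted linear-in-age fit to ages 8–17
projected down to ages 2–7, which requires the linear trend to hold outside
its support; the implementation refuses to extrapolate unless
`allow_extrapolation=True` is passed, making the hazard explicit).

### Height-percentile matching

The external tables are columned on height percentiles (default labels 5,
10, 25, 50, 75, 90, 95). A child's height percentile is, by default, the
survey-weighted fraction of same-age same-gender children with height less
than or equal to theirs (the "≤" tie convention, fixed for determinism);
an LMS growth-reference table (columns `age,gender,L,M,S`) may be supplied
instead to reproduce published growth-chart percentiles. The nearest column
is matched by absolute distance, ties broken toward the smaller label.
Children with missing height are routed to the 50th-percentile column and
counted in the log — the median is the neutral choice. Matching is treated
as a unit attribute computed once on the full sample; resamples redraw
imputations and re-estimate model parameters but do not recompute
percentiles (a child's height percentile is a characteristic, not a fitted
parameter, and recomputing it inside every resample would add an order of
magnitude of cost for a second-order contribution to the variance).

### AIPW variant

For covariate-adjusted analyses (age, gender, height, body weight), `e1`
can be estimated by augmented inverse probability weighting: a weighted
logistic model for `Pr(R=1 | V)` and a weighted outcome regression `m(V)`,
combined as the weighted mean of `r·y/π̂ − ((r − π̂)/π̂)·m̂(V)` over
positive-region units. The estimator is consistent when either nuisance
model is correct (double robustness, verified by simulation in the test
suite). Survey weights enter both the nuisance fits and the final mean; the
alternative of weighting only the final mean is a documented variation, not
implemented as a switch. Fitted probabilities are truncated below at 0.01
with a logged count — inverse weights are otherwise unstable, and the data
cannot distinguish a tiny π from zero. With saturated models on both sides
and a discrete covariate, AIPW collapses algebraically to the saturated
g-computation estimate; the saturated propensity is therefore computed in
closed form (per-age weighted observation rates), which also avoids
logistic separation when an age stratum is fully observed. Complete cases
missing height or body weight are excluded from the covariate outcome fit
(logged); their augmentation term uses the mean prediction.

### Bounds

When no external information is trusted, `mu(e0) = e1·p1 + e0·p0` is swept
over a user grid (default 70–120 mm Hg, a generous range for mean SBP in
ages 2–7). The curve is affine with slope `p0`; its endpoints bound `mu`
whenever the true `e0` lies inside the grid. CIs for the curve bootstrap
`(e1, p1)` jointly and hold the grid value fixed.

## Resampling inference

Point estimates and 95% CIs come from `B` with-replacement resamples
(default 10,000 for analysis; tests use hundreds): each resample re-fits
the statistical model, re-estimates region shares, and redraws one
imputation per never-observed unit (`draws_per_unit = 1`, configurable
upward to shrink imputation noise in the point estimate), then recombines.
The B estimates are summarised by median and 2.5/97.5 percentiles, with
linear interpolation between order statistics (numpy's default, type-7) as
the single declared quantile convention.

Default scheme `uniform_keep_weights`: rows are resampled uniformly and
retain their survey weights, so every downstream estimator stays weighted.
`weight_proportional` (draw with probability ∝ weight, reset weights to 1)
is available for comparison. Degenerate resamples are handled explicitly
rather than silently: a resample that loses an entire region contributes
the other region's mean (its estimated share is exactly zero); a resample
in which an age 8–17 is present but has no complete cases falls back to the
overall positive-region complete-case mean for that age, with the event
counted and reported; resamples in which an estimator's preconditions fail
outright are dropped and counted, and more than 5% failures aborts with a
breakdown. The procedure does not model survey clustering, so on clustered
designs the intervals will be anti-conservative.

## Agreement diagnostic

The external tables also cover ages 8–17, where the outcome is observed.
For each such age the diagnostic compares the survey-weighted complete-case
mean with the weighted mean of mathematical-model draws for the same units
(all positive-region units of that age, exactly as the model would be
deployed). Differences are paired within each resample — both quantities
are recomputed on the same resample before differencing, which removes the
shared sampling variation — and summarised by percentile CIs. Per-age CIs
are reported without multiplicity adjustment: this is a diagnostic display,
not a family of tests, and adjusted intervals would understate
disagreement. The check cannot validate the external information below age
8, where no comparison exists; it can only falsify it on the overlap.

## Synthetic-data generator

The generator emulates the survey structure the estimators target: ages
uniform on 2–17 (so the nonpositive share is 6/16 = 0.375, near the
motivating survey's weighted 34%); gender balanced; height normal with mean
linear in age (≈ 78 + 5.5·age + 2·male cm, SD 7); body weight linear in
height; SBP normal with mean `80 + 1.5·age + 2·male + 0.05·height` and
residual SD 10 mm Hg (population mean ≈ 101.8, rising ≈ 1.9 mm Hg/year
overall); observation probability `expit(2.5 − 0.05·(age − 12))` for ages
8–17 (≈ 8% missing at random) and exactly zero below 8; survey weights
`0.5 + Gamma(2, 0.75)`, independent of SBP given age so the weighted
estimand equals the generative mean. The emitted reference table evaluates
the true conditional SBP distribution at each height-percentile column, so
with perturbation `delta = 0` the external information is exactly accurate,
and `delta ≠ 0` shifts every table mean by that amount — the diagnostic
should recover `−delta`.

What the generator does *not* emulate: cluster sampling, oversampling and
nonresponse-adjusted weights, non-normal SBP tails, reporting digit
preference, and correlation between weights and outcome. Passing tests
therefore demonstrate correctness of the estimators under the stated laws,
not robustness to survey design features the method itself excludes.

## Numerical choices and problem sizes

- All randomness flows through `numpy.random.default_rng` seeds; identical
  seeds give byte-identical outputs (CSV floats are written as `%.17g` and
  parsed in round-trip mode).
- Test-suite simulation studies use n = 1000–2000 with B = 500 and 200
  replicates — sizes at which the Monte-Carlo error of a bias estimate is
  ≈ 0.02 mm Hg, an order of magnitude below the effects being detected.
- The bootstrap hot path is vectorised (per-age weighted means via
  bincount), so a 500-resample run on n = 2000 takes well under a second.
- Validation is strict and early: nonpositive weights, inconsistent
  region/missingness indicators, duplicate keys, and `P90 < P50` reference
  rows all fail at load time with the offending units named.

## Known limitations

- No design-based (cluster/stratum) variance; intervals assume independent
  sampling within the resampling scheme.
- The height-percentile matching discretises to the table's columns; with
  the default seven columns the induced bias is far below sampling noise,
  but coarser tables would widen it.
- Multiple nonpositive dimensions (e.g. age × another never-observed
  stratum) are not supported; the region indicator is one-dimensional.
- The mathematical model imputes SBP directly from marginal tables; it does
  not model intermediate processes (e.g. medication effects), which richer
  external information would require.
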