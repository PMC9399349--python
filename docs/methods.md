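# Methods

## The estimation problem

On a twice-daily milking schedule a cow's daily milk yield (DMY) is
`y = x_AM + x_PM`. In an AM-PM recording plan only one session is weighed
per test day, so `y` must be estimated from the measured yield `x`, its
milking interval `t` (hours since the previous milking), and days in milk
`d`. Doubling (`ŷ = 2x`) is exact only when both intervals are 12 h; real
AM intervals run longer than PM intervals (the two must sum to ~24 h), so
the measured milking systematically over- or under-represents half the
day. Every model in this package is a different way of correcting that.

All regressions center DIM at a reference day `d0 = 158` (configurable),
so intercepts are interpretable at mid-lactation. Sessions can be fitted
jointly (session-specific intercepts, shared slopes — roughly halves the
coefficient standard errors) or separately (everything per session).

## Model-by-model notes

* **M1 (cell-mean ACF).** The correction `z = y − 2x` is averaged within
  each (session, interval class, lactation month) cell. For a saturated
  two-way layout the estimated effect sum equals the cell mean, so the
  package estimates cells directly by group means rather than solving a
  constrained ANOVA. Empty cells fall back to the session's marginal
  class mean (then the session mean) and are flagged imputed — the
  fragility of cell-mean ACF in sparse classes is the point of comparing
  it with the regression versions.
* **Sign convention.** `z = x_other − x_measured = y − 2x`, so
  `ŷ = Δ + 2x` is unbiased by construction. ("Difference between AM and
  PM yield" is direction-ambiguous; this reading makes the estimator an
  identity in expectation.)
* **M2 vs M3.** M2 fixes the single-yield coefficient at 2 (equivalently:
  OLS of `y` with offset `2x`); M3 estimates it (`b̂ ≈ 1.75` on realistic
  data). Constraining M3's `b` to 2 reproduces M2's coefficients exactly;
  this identity is a test.
* **Factor-table conventions.** The default ACF discretization is
  `Δ_j(k) = α̂_j + β̂·t̄_j(k)`; a second convention additionally absorbs
  `γ̂·(mean training DIM in class − d0)` into the table. Both are
  implemented and the table records which was used, because the two
  published forms disagree and neither should be chosen silently.
* **M5.** Bulk (not per-cow) proportions `Σx/Σy` per class, smoothed by an
  unweighted quadratic in the class midpoint by default; count-weighted
  smoothing is an option. The smoothed denominator must stay positive over
  populated classes — a violation is an error, never a silent negative
  factor.
* **M6.** Per-class no-intercept OLS of `y` on `x` and `(d−d0)` (closed
  form), then a straight line through the reciprocals `1/b̂_j(k)`. The
  per-class DIM slope `γ̂_jk` is carried into prediction.
* **M7B's DIM adjustment** adds the ratio-scale `γ̂` on the kg scale, as
  the cited construction prescribes; this is dimensionally questionable
  and can be switched off (`m7b_dim_adjust=False`).
* **M8.** Natural-log OLS of `log y` on session intercepts, `t`, `(d−d0)`
  and `log x`. The factor form multiplies by the lognormal moment
  correction `ρ_j(k) = exp(½(V(y)/E(y)² − b̂·V(x)/E(x)²))` computed from
  per-class training moments; classes with fewer than two records borrow
  the nearest populated class's moments, flagged imputed.
* **`d0(k)`** in the factor-strategy DIM adjustments is taken as the global
  `d0`; per-class mean-DIM centering is available as the `table2` ACF
  convention.

## Interval classes

Half-open 1-h bins with edges at 5.5, 6.5, …, 20.5 h, so midpoints fall on
integer hours (6…20) and the class containing 12 h is centered at exactly
12.0 h. This alignment matters: under symmetric milkings every
multiplicative factor equals 2 *at 12 h*, and a grid with edges on integer
hours would put the "12-h class" midpoint at 12.5 h, where the factor is
≈1.93, not 2. Out-of-grid intervals are clamped to the terminal class and
flagged rather than dropped.

## Cross-validation

Default plan: 10 folds × 30 replicates (tests and examples use reduced
plans such as 5 × 3 to stay fast). Folds are drawn at the record level by
default; cow-level folding is available to prevent a cow's records from
straddling train and test. All fitting — including factor tables and
per-class moments — uses the training folds only. Each record is tested
exactly once per replicate, so pooling a replicate's k test folds gives
that replicate's out-of-sample error.

Across replicates, `Var` is the spread of each record's estimates around
its replicate mean, `Bias²` the squared distance of that mean from the
truth, and `MSE = Var + Bias²`; both routes to the MSE are computed and
the identity asserted at 1e-8 relative tolerance. `σ²` in
`R² = σ²/(σ² + MSE)` defaults to the sample variance of actual DMY over
the full dataset ("true phenotype" is ambiguous); a per-fold variant is a
setting. Model comparisons use paired t-tests on per-replicate R² or
per-record R²; zero-variance differences are reported as degenerate.

## Synthetic data

The generator emulates the features of restricted US Holstein/Jersey
test-day records that drive the estimators, per breed profile:

| Parameter | Holstein | Jersey | Why |
|---|---|---|---|
| mean AM interval (h) | 12.34 | 12.95 | published means (12.3/13.0 AM); PM is the 24-h complement, giving AM−PM gaps of 0.69 h and 1.90 h |
| interval sd (h) | 1.0 | 1.0 | bell-shaped published distributions |
| interval bounds (h) | (6, 20) | (6, 20) | published ranges |
| interval recording noise sd (h) | 0.15 | 0.15 | measured pairs sum to ≈24 h, not exactly |
| mean daily yield (kg) | 31.7 | 23.7 | published AM+PM session means |
| cow effect sd (kg) | 4.0 | 3.0 | between-cow spread; scaled with yield |
| DIM slope (kg/d) | −0.02 | −0.02 | mild post-peak decline; Wood curve optional |
| residual CV | 0.08 | 0.08 | day-to-day lognormal noise, keeps yields positive for the log model |
| udder-fill time constant τ (h) | 30 | 30 | saturating accumulation `g(t) = 1 − e^{−t/τ}`: session yield concave, not linear, in interval |
| logit share jitter sd | 0.08 | 0.08 | within-day partition noise that conserves the daily total |

The AM share of the day is `g(t_AM)/(g(t_AM)+g(t_PM))`, jittered on the
logit scale — so `x_AM + x_PM = y` holds to machine precision, yields stay
positive, and the AM yield exceeds the PM yield on average because AM
intervals are longer and `g` is concave. Measured sessions alternate
within cow. Parity labels approximate the published 35/64/1% split and
serve only as covariates.

What the generator does **not** emulate: herd/season/year structure,
3×-milking schedules, milk components, and the full heterogeneity of field
data (e.g. heavy interval tails, herd-specific milking routines). Passing
tests therefore demonstrate correctness of the estimators and the
evaluation machinery under a controlled data-generating process, not
field-data accuracy levels; published accuracy tables from restricted
records are not reproducible here and are not targeted.

## Splines and curves

λ is selected by GCV (scipy's `make_smoothing_spline`); a fixed λ is
accepted. REML selection is not provided. Numerical choices: abscissae are
collapsed to weighted means per distinct value; for mean curves the
interval axis is pre-rounded to 0.05 h because GCV over thousands of
densely spaced distinct abscissae is ill-conditioned in the banded solver;
the λ→∞ linear limit is numerically reliable up to λ ≈ 1e6–1e9 at these
data scales. Curves are never extrapolated outside the observed interval
range.

Model mean-yield curves average the model's prediction at each grid
interval over the empirical (x, d) distribution of records whose interval
falls in the local 1-h class (so M0's curve equals twice the local mean
yield, making the comparison with the CSS mean of actual DMY
well-defined); plug-in-at-means evaluation is an option. Curve agreement
is summarized by the mean absolute deviation on the common grid.

## Known limitations

* Twice-daily milking only; the types admit 3× extension but no 3× logic
  exists.
* M1 is limited to interval class × lactation month; wider
  cross-classifications (whose cell count the `acf_cell_count` utility
  exposes) are deliberately not fitted.
* Indirect AM-from-PM factors, factors from the quadratic model (M4), and
  log-scale ACF for the exponential model are out of scope.
* The generator's calibration targets interval means; the emergent AM−PM
  yield gap (~1–2 kg under defaults) is plausible but configurable rather
  than pinned, since published summaries disagree on its magnitude.
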