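# Methods

This note records the models, the default parameters and where they come
from, the numerical choices, and what the simulations can and cannot show.

## Estimand

All effects are substitution (reallocation) contrasts: move δ units from a
reference component into an exposure component, hold every other component —
and therefore the total — fixed, and take the difference in expected outcome.
The exposure/reference pairs are MVPA-for-LPA (time use, δ = 1 and 10 min)
and carbohydrate-for-protein (diet, δ = 1 and 100 kcal). Every contrast
starts from a frozen *population start composition*: the component-wise
geometric mean of a large calibration sample (n = 10⁶, fixed internal seed
`CALIBRATION_SEED`), the conventional reference point in compositional
analyses. The start is deliberately not re-closed to the fixed total — the
sum of geometric means is slightly below it — because the contrast is defined
at the raw geometric-mean point. For non-linear mechanisms and models the
effect depends on this start point; estimates from a different start are
different estimands and must be computed explicitly.

## Exposure generators

**Fixed totals (time use).** Components are jointly dependent because they
must close to 1440 min/day. Generation is iterative: the first component is
its target mean plus Gaussian noise; each subsequent component takes its
target share of the still-unallocated time plus noise; the last component is
the exact remainder. Rows with any non-positive component are rejected and
redrawn whole, preserving the dependence structure; a sustained rejection
rate above 50% raises a configuration error. Defaults: order Sleep → SB →
LPA → MVPA(remainder), target means 564/541/313/22 min/day, noise sd 10% of
the target mean except LPA. LPA's noise propagates almost one-for-one into
the MVPA remainder (mean 22 min), so its sd is capped at 7 min/day; this
keeps MVPA's induced sd near 7 min and the rejection rate near 0.1%. The
remainder component absorbs the closure constraint, which is why the
smallest component is generated last.

**Variable totals (diet).** Components are independent normals (target means
1000/600/100/300 kcal/day for carbohydrate/fat/alcohol/protein, sd 10% of
the mean, whole-row rejection of non-positive draws) and the total is the
exact row sum, mean 2000 kcal/day. Independence is the point: with a
variable total, changing one component does not force a change in any other.

Both generators are deterministic given `(config, n, seed)`. Study replicate
r draws from seed streams `SeedSequence([master_seed, r, stream])`, so any
replicate is reproducible in isolation.

## Outcome mechanisms and their calibration

FPG is generated as a noise-free linear predictor plus N(0, σ²) residuals,
σ = 0.5 mmol/l by default (a plausible residual FPG spread). Three
mechanisms per scenario:

* linear in the raw amounts (reference component absent for fixed totals;
  protein entering only through the total for variable totals);
* linear in log₂ amounts;
* linear in unscaled ILR pivot coordinates of the full composition.

Coefficients are solved from the stated effect targets rather than fixed by
hand. The 1-unit substitution effect is constrained to be identical across
mechanisms (−0.020 mmol/l per min; +0.004 mmol/l per kcal). For the linear
and fixed-total log₂ mechanisms this pins the focal coefficient uniquely
(`solve_focal_coefficients`); the substitution contrast is linear in every
coefficient, so the solution is closed form. For the mechanisms where the
contrast moves two or more terms (log₂ with a variable total; both ILR
mechanisms), the 1-unit constraint alone is underdetermined, and the big
reallocation's effect (−0.157, +0.284, +0.510 mmol/l) is used as a second
constraint to solve a secondary coefficient jointly
(`solve_twopoint_coefficients`). Remaining coefficients keep documented
presets of modest, plausible magnitude (e.g. a small adverse sedentary
effect); every closed-form quantity checked by the tests is invariant to
them. The intercept is then calibrated so the population mean outcome is
5.5 mmol/l (mean of the noise-free predictor over the calibration sample);
additive noise does not shift the mean, so large-sample means match the
target to Monte Carlo error. Truth mechanisms serialize to YAML so a study
is reproducible from one file.

## Model battery and substitution estimates

Parametric families are ordinary least squares fits on the transformed
designs listed in `codasub.models`. ILR regressions use the unscaled pivot
form `ln(p_j / gm(p_{j+1}…p_D))`; the orthonormal convention differs only by
fixed per-coordinate factors, so fitted values and prediction contrasts are
identical and the choice is cosmetic. Ratio families for fixed-total data
divide by the constant 1440 (dividing by a constant is a pure rescaling,
which is why these models are exactly equivalent to the linear leave-one-out
fit); variable-total ratio families divide by the per-row total.

Every family's effect estimate is the same prediction contrast: predict at
the reallocated start composition, predict at the start, difference. The
total is conserved by the ±δ reallocation, so `Total` terms cancel; for
non-GAM families the contrast reduces to explicit coefficient expressions,
which the tests verify against the fitted predictions to 1e-10.

**Additive models.** GAM families are fitted by penalized least squares on
cubic B-spline bases (statsmodels `BSplines`, centering constraints, k basis
functions per term) with the integrated-squared-second-derivative penalty.
A single smoothing parameter λ shared across terms is chosen by minimizing
GCV = n·RSS/(n − edf)² over a 29-point log grid spanning essentially
unpenalized to essentially linear fits; each term's penalty is normalized so
covariates on very different scales receive comparable shrinkage. Effective
degrees of freedom are the trace of the hat matrix and enter the Gaussian
AIC, n·ln(RSS/n) + 2(edf + 1), used to select the basis dimension k over
{5, 10, 15, 20, 25, 30} (ties to the smallest k). In a Monte Carlo run, k is
selected once per (truth, family) cell on a pilot replicate and then held
fixed, keeping the fitted model class constant across replicates; λ is
re-selected per fit. Boundary knots are pushed 20% of the data range beyond
the observed minimum and maximum so that contrast endpoints slightly outside
the training data (protein 100 kcal below a typical day can be) remain
defined; such predictions use the natural polynomial extension of the basis
and are raw local predictions, with no extrapolation control. The engine is
cross-checked against R's `mgcv` on a fixture (`tests/test_gam.py`);
agreement is expected in the fitted mean function, not coefficients, since
`mgcv` uses thin-plate/REML machinery.

## Monte Carlo design and summaries

A study cell is (truth mechanism × family × δ). Per replicate: fresh
exposures, fresh outcome noise, all families fitted, contrasts taken from
the frozen start. Cells are summarised by the median estimate and the 95%
simulation interval (empirical 2.5th/97.5th centiles), next to the
mechanism's closed-form effect and the relative deviation
|median − truth| / |truth| (reported as absolute deviation, flagged, if a
truth is exactly zero — no default cell is). Failed fits are recorded as
missing with their error and replicate seed, never silently dropped; a cell
failure rate above 1% aborts the run. Summaries are invariant to replicate
ordering.

The headline design is 10,000 replicates × 1,000 observations. The package
default is 1,000 replicates (medians and interval endpoints are stable well
below 10,000), and the test suite uses 150–300 replicates for parametric
families and 60–150 for GAM families; the acceptance script runs the linear
leave-one-out benchmark at 1,000 × 1,000.

## What the generators do and do not emulate

The synthetic data reproduce the compositional structure (exact closure for
time use, additive totals for diet), realistic component means, strictly
positive values, and known outcome mechanisms with a common 1-unit effect.
They do **not** include confounding, measurement error, non-normal noise,
correlated macronutrients, or weekday/season structure — so passing
benchmarks demonstrate estimator behaviour under clean conditions, not
robustness in real data. Noise sds are deliberately narrower than real
spreads (10% of the mean, capped) to keep all values positive; narrower
spreads also mean weaker curvature across the observed range, which makes
smooth models shrink toward linear fits more readily than they might in
wider real data.

## Known limitations

* Shared-λ GCV is cruder than per-term REML smoothing; it reproduces the
  qualitative GAM behaviour (unbiased medians, wide 1-unit intervals,
  leave-one-out bias with a variable total) but individual GAM fits can be
  over- or under-smoothed relative to `mgcv`.
* Non-focal preset coefficients are conventions, not estimates; quantities
  that depend on them (e.g. cross-mechanism estimates of misspecified
  families) are meaningful only qualitatively.
* The pivot order and the left-out reference are fixed to the conventional
  choices (MVPA-first, LPA/protein as reference) and configurable, but the
  defaults are the only configurations exercised by the benchmark.
* Single-dataset effect estimates carry no standard errors; uncertainty is
  summarised only across simulation replicates.
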