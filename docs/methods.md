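# Methods

## Model and search

A biological record made on date `d` (one response value, optional
covariates, optional group label) is linked to a daily climate series
through a *climate matrix*: entry `(r, j)` is the climate value `j` days
before record `r`'s adjusted date. Offsets are 0-based, windows are closed
intervals `[end, start]` in days before the adjusted date, and day 0 is
the adjusted date itself. Under *absolute* windows every record's date is
moved to a user-supplied reference day/month in its own year (all records
in a year then share one climate history); *relative* windows leave dates
untouched. A reference day falling after the measurement is applied
verbatim but logged, since the window then covers post-measurement
climate.

For each candidate window the in-window climate is reduced row-wise by an
aggregate statistic (mean, max, min, sum, or the least-squares slope of
climate against calendar time, in climate units per forward day), appended
to the baseline model under a chosen functional form (linear, quadratic,
cubic, log, inverse — log/inverse error on non-positive aggregates), and
the refit is scored by

    ΔAICc = AICc(climate model) − AICc(baseline),
    AICc  = −2 log L + 2ρ + 2ρ(ρ+1)/(N − ρ − 1),

with natural logarithms. ρ counts every estimated parameter including the
gaussian residual variance (intercept-only gaussian: ρ = 2); this constant
convention cancels in ΔAICc differences between nested gaussian models up
to the small-sample term. Negative ΔAICc favours the climate model, and
the model set is ranked ascending; ties are broken toward the shorter
window, then the later (smaller) end offset — a deterministic rule chosen
because equal-ΔAICc windows are scientifically interchangeable and the
shorter one is the more parsimonious statement of timing.

The search over range `(r_max, r_min)` enumerates all `m(m+1)/2` windows
(`m = r_max − r_min + 1`), inclusively: a one-year daily range (365, 0)
yields 67,161 candidates. Windows whose model cannot be fitted (undefined
transform, collinearity) are kept as flagged rows with missing ΔAICc so
the set size is always `m(m+1)/2`; weights are computed over the finite
rows only.

Gaussian baselines with a linear climate term take a closed-form OLS path
vectorized across all windows: after projecting the baseline design out of
response and climate, the climate slope, its standard error and the full
residual sum of squares follow from residualized cross-products. The path
is algebraically identical to refitting each window with statsmodels,
which the generic path (other families, functional forms, centring) does
and the unit tests cross-check to 1e−8.

### Coarser time resolution

Weekly/monthly analysis aggregates the daily matrix into blocks counted
backwards from the adjusted date (block 0 ends on the adjusted date; a
block's value is the mean of its member days; months use calendar month
arithmetic per record). This preserves the "days before" semantics at
coarser resolution. Missing climate days anywhere in a required span are
a hard error listing the dates — no imputation, since silent interpolation
would bias aggregates.

### Within-group centring

The climate aggregate can be split into group means and within-group
deviations (deviation + mean reconstructs the aggregate exactly;
deviations sum to zero per group); the model then carries two climate
terms with separate slopes, separating within- from between-group climate
sensitivity. Zero between-group variance makes the mean term collinear
with the intercept and is reported as a fit error rather than silently
dropped.

## Weighted windows

Instead of a uniform weight inside a hard-edged window, a parametric
density defines a weighted climate mean. Densities are evaluated on
normalized time `t ∈ [0, 1]` across the offset range — at the midpoint of
each day's interval, `t_j = (j − r_min + ½)/m` — and renormalized by their
sum, so the weights are exactly a discrete distribution (non-negative,
summing to one) and a scale of 0.2–0.3 is meaningful regardless of whether
the range spans 60 or 365 days. Small `t` is recent climate. Two families
are provided: Weibull (shape > 0, scale > 0, location shifting the support;
shape 1 gives exponential, fading-memory decay) and GEV in the standard ξ
parameterization (the Gumbel limit is taken for |ξ| < 1e−6, where the
density is continuous in ξ). A uniform weight vector over `[end, start]`
reproduces the sliding search's mean-statistic ΔAICc for that window
exactly — the sliding search is the degenerate special case.

(shape, scale, location) are optimized by bounded quasi-Newton search
(L-BFGS-B, finite-difference gradients; the method is switchable). Default
bounds in normalized time are shape ∈ [0.01, 20] (Weibull) or ξ ∈ [−5, 5]
(GEV), scale ∈ [0.01, 5], location ∈ [−5, 5], user-overridable. Parameter
sets with an all-zero density on the grid return a large penalty (1e10) so
the search backs off; non-convergence is flagged on the result, which
always carries the best parameters seen. The optimizer report (iterations,
evaluations, objective trace) is returned for diagnosis.

A caution on interpretation: the triple (shape, scale, location) is only
weakly identified on the discretized unit interval — distinct triples can
produce near-identical discrete weight curves (a ridge). The recovered
*curve* is the meaningful output; raw parameter values should not be
over-read, and the tests assert curve recovery rather than parameter
recovery. Sensible starting values (inspected with `explore`) matter:
starts whose density mass lies far outside the window can land on a flat
penalty plateau.

## Multi-model inference

Akaike weights `w_i = exp(−(Δ_i − Δ_min)/2) / Σ_j exp(−(Δ_j − Δ_min)/2)`
are computed over the finite rows of the ranked set. The level-γ
confidence set is the longest prefix whose cumulative weight is ≤ γ (the
record crossing γ is excluded; if the single best model already exceeds γ
the set is that model, so it is never empty). C is the set size as a
fraction (or percentage) of all tested windows. Window timing is
summarized by the weight-weighted median start and end within the set
(first value whose cumulative within-set weight reaches ½; a plain median
is available), and the model-averaged slope is `Σ β_i w_i` with weights
taken over the *full* set, deliberately not renormalized — the averaged
slope is shrunk by the weight mass outside the set.

## Randomization error metrics

`randwin` permutes the biological date column (responses and covariates
stay on their rows, so covariate structure and climate autocorrelation are
preserved while the climate–response link is broken), reruns the chosen
analysis, and records the best ΔAICc — plus C for sliding runs. A
permutation that happens to reproduce the original order is resampled
once, then accepted.

`P_ΔAICc = (r + 1)/(n + 1)` where `r` counts randomized best ΔAICc values
at or below the observed one — a continuity-corrected permutation rank
that is never exactly zero and is reported as `< 1/(n+1)` when `r = 0`.
Under the null it is uniform on its lattice, which the tests verify by
Kolmogorov–Smirnov over 200 null datasets.

`P_C` evaluates a fixed logistic calibration of `ΔC = C_obs −
median(C_rand)` (proportion scale; `ΔC ∈ [−1, 1]`) and sample size N:

    P = 1 / (1 + exp(b0 + b1·ΔC + b2·N + b3·ΔC·N)),

with (b0, b1, b2, b3) = (−0.54, 1.95, 0.08, 0.31) for plain searches and
(−0.62, 11.56, 0.06, 6.88) for 10-fold cross-validated searches. The
calibration's larger CV coefficients are only plausible with ΔC as a
proportion, which is why proportions are the internal scale (a
`percent_scale` switch accepts percentages). As printed above the form
evaluates near 1 for strong signals — it behaves as the probability that
the signal is real — while worked analyses conventionally quote the
complement, on which small values mean a credible signal. Both
orientations are exposed (`verbatim` and `reported`); the classification
rule "signal when P_C < 0.5" applies to the reported orientation, and the
misclassification machinery uses it. The companion shift
`ΔD = ΔAICc_obs − median(ΔAICc_rand)` is available for diagnostics.

## k-fold cross-validation

For gaussian responses the per-window score can be replaced by an
out-of-sample version: rows are partitioned uniformly at random into k
near-equal folds (seeded; the seed is part of the config and logged); per
fold, window model and baseline are fitted on the training rows and scored
on the test rows by

    AICc = N·log(MSE_test) + 2ρ + 2ρ(ρ+1)/(N − ρ − 1)

with N the *total* sample size, and the fold-wise ΔAICc values are
averaged. Reported coefficients and R² still come from a full-data fit of
each window; only selection is cross-validated. CV is restricted to
gaussian families because the score is MSE-based — requesting it elsewhere
is an explicit error, not a silent deviance substitute.

Two properties of this estimator, measured on synthetic data at N = 47,
true R² = 0.2 (150–200 datasets): (i) for a *fixed* window with a real
signal the CV ΔAICc is less negative than the in-sample ΔAICc in median —
CV removes the optimism of scoring a model on its own training data; and
(ii) the median R² of the CV-selected best window is closer to the truth
than without CV (≈ 0.23 vs ≈ 0.28 against 0.2). Note that the *minimum*
of the CV scores across hundreds of windows is itself subject to selection
noise, so the best-window CV ΔAICc is not guaranteed to be less negative
than the best-window in-sample ΔAICc on any given dataset; the bias
reduction is a selection-level, distributional property, which is how the
tests phrase it.

## Synthetic data

The generator emulates a multi-decade phenology study: a daily AR(1)
gaussian climate series `x_t = φ x_{t−1} + √(1−φ²) ε_t` (mean 0, unit
marginal variance, lag-1 autocorrelation φ, default 0.5 — moderate
persistence typical of daily temperature anomalies), and one record per
year on a fixed measurement day (default 20 May, 47 years from 1966) with

    response = intercept + β · mean(climate in the true window) + ε,

true window (30, 10) days back and β = −3 by default (a chaffinch-like
"earlier with warmth" slope on an intercept of 100). The noise variance
solves `R² = Var(signal)/(Var(signal) + Var(ε))` using the realized
variance of the windowed means, so the target R² is a property of each
generated series; `target_r2 = 0` forces β = 0 (pure null with unit
noise), and a `noise_sd` override supports the noiseless boundary case
used by exact-recovery tests. Everything is reproducible from
(spec, seed).

What the generator does *not* emulate: trends or seasonality in climate,
spatial replication, observation error in dates, non-gaussian responses,
multiple or interacting climate signals. Passing tests therefore show the
machinery is correct and calibrated under clean single-signal conditions,
not that any field dataset satisfies those conditions.

`performance_study` runs the full pipeline (search + 5-repeat
randomization + P_C classification at 0.5) over a grid of sample sizes and
signal strengths and tabulates false-positive/negative rates, median
estimated R² and window-recovery overlap. At desk scale (25 datasets per
cell, range 40 days) the qualitative patterns are: false negatives fall
with N and with true R², false positives fall with N, and CV shrinks the
R̂² bias at every N.

## Numerical choices and limitations

- Problem sizes in tests and the acceptance script are desk-scale (ranges
  ≤ 60 days, 100–200 datasets per property) — large enough for the
  distributional claims, small enough to run everywhere; the search
  itself handles full-year ranges (67,161 windows) in seconds on the
  vectorized path.
- Degenerate climate terms in the vectorized scan are detected by a
  relative threshold on the residualized sum of squares (1e−10 of the
  squared data scale) and flagged rather than fitted.
- Fold assignment uses `numpy` Generator permutation with near-equal fold
  sizes; k must satisfy 2 ≤ k ≤ N and empty folds are an error.
- The permutation p-value uses the (r+1)/(n+1) rank, never exactly 0.
- Dates are proleptic-Gregorian ordinals parsed strictly as dd/mm/yyyy;
  malformed entries name the offending row.
- Sub-daily climate, gridded climate, multiple simultaneous climate
  variables, mixed-effects and proportional-hazards baselines, and
  spline/LASSO weight functions are out of scope; the model adapter
  (refit-with-extra-terms reporting log L/ρ/N) is the extension point.
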