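# Methods

## Model and estimators

One subject's heart rate on day *i* is a smooth latent curve observed with
homoscedastic noise at irregular timestamps `t_ij` (hours since local
midnight, closed interval [0, 24]):

    y_ij = x_i(t_ij) + eps_ij,   eps_ij ~ iid N(0, sigma^2)
    x_i(t) = Phi(t)' C_i,        C_i ~ N(C, Sigma_C)

`Phi` collects P B-spline basis functions. Everything the package estimates
is a closed-form method of moments — nothing is optimized:

* per-day coefficients by OLS, `C_i^ = (Phi_i Phi_i')^{-1} Phi_i Y_i`;
* `sigma^2^` as the average over days of `e_i'e_i / trace(I - H_i)`, with
  `H_i` the hat matrix — unbiased because each summand has expectation
  `sigma^2`;
* the coefficient mean `C-bar` (plugged in as the prior mean for
  calibration) and the debiased covariance
  `Sigma_C^ = S_C - (sigma^2^/M) sum_i (Phi_i Phi_i')^{-1}`, where `S_C` is
  the outer-product sample covariance with divisor M−1. The subtraction
  removes the mean least-squares estimation noise, so
  `E[Sigma_C^] = Sigma_C`.

Calibration against a new day `Y*` is exact Gaussian conditioning of the
coefficient prior `N(C-bar, Sigma_C^)` under the same noise model, giving
`C*` and `Sigma*` in covariance form (see the `calibrate` module docstring)
and the posterior GP used for denoising and gap imputation.

### Assumptions, and where they are knowingly violated

The noise model is homoscedastic and Gaussian; motion artifacts are neither.
No explicit outlier-rejection step is applied: artifact suppression is the
basis smoothing itself, and artifact energy that survives smoothing inflates
`sigma^2^` (visible in the worked example: estimated sd 6.5 bpm vs 3 bpm
sensor noise at the default artifact settings). This keeps every estimator
in closed form; the cost is a conservative (wider) likelihood during
calibration. Day-to-day coefficient draws are exchangeable — no circadian
phase drift, weekday effects or autocorrelation across days.

## Basis choices

* Clamped B-splines, uniform interior knots, order 4 (cubic), P = 13 by
  default; all config-exposed (`n_basis`, `spline_order`, `t_period`).
  Uniform clamped knots are the standard functional-data default; nothing in
  the method depends on the knot layout beyond `Phi`.
* Evaluation is delegated to `scipy.interpolate.BSpline.design_matrix`; the
  right domain endpoint is included, and the basis sums to one everywhere on
  the closed domain (property-tested).

## Numerical policy

* Per-day Gram matrices are declared numerically singular at relative
  condition 1e10 (double-precision heuristic); such days fall back to the
  minimum-norm least-squares solution and are flagged `rank_ok=False`.
* Distinct from that numerical flag, baseline pooling excludes days whose
  Gram condition exceeds `max_day_gram_cond` (default 1e6). Block
  missingness can cover nearly all of one basis function's support, leaving
  that coefficient statistically unidentified while the matrix is still
  invertible in floating point; a single such day can dominate the pooled
  mean with coefficients orders of magnitude off scale. The guard surfaces
  these days in `excluded_days` instead of letting them poison the baseline.
  The threshold is a variance argument, not a float one: at condition 1e6 a
  coefficient direction's sampling sd is ~1000× the best-determined one.
* Days with residual degrees of freedom `trace(I - H) <= 0.5` are excluded
  from `sigma^2^` (its denominator).
* `Sigma_C^` can be indefinite in finite samples; the raw estimate is kept
  for diagnostics and an eigenvalue-clipped PSD repair (the nearest PSD
  matrix in Frobenius norm) is used wherever the covariance enters a
  quadratic form or the posterior.
* The N×N calibration system is solved by Cholesky factorization with a
  one-shot jitter fallback (1e-10 × mean diagonal) — never explicit
  inversion. `Sigma*` is symmetrized and negative eigenvalues from float
  cancellation are clipped.
* Ties and duplicates: timestamps are stably sorted; exact duplicates are
  retained (least squares handles them). Degenerate inputs (empty day,
  all-identical timestamps) are flagged or rejected per operation contracts.
* Minimum observations per day for baseline pooling: `n_basis + 2` by
  default — below that the per-day fit is an interpolation with no residual
  information.

## The synthetic-data generator

The generator emulates the structure of multi-week paired-sensor HR
collection so that every estimator can be validated against known ground
truth:

* a smooth diurnal template (nocturnal trough ≈ 57 bpm, afternoon peak
  ≈ 82 bpm) projected onto the basis, plus per-subject variation — a level
  offset (sd 7 bpm, projected back into a [45, 110] bpm envelope) and mild
  shape perturbation (sd 2 bpm per coefficient). Subjects therefore differ
  mostly in level, which is what makes a population-mean estimator clearly
  worse than subject-specific ones, mirroring the monitored-cohort setting;
* day coefficients `C_i ~ N(coef_true, coef_cov_true)` with a smooth
  covariance scaled to ≈ 3 bpm between-day sd at curve level;
* sensor noise sd 3 bpm; motion artifacts as Bernoulli(0.05) shocks of sd
  25 bpm (optionally one-sided positive). The artifact rate and magnitude
  are placeholders — no quantitative characterization of PPG artifacts was
  available to copy — and are config-exposed;
* missingness deleted in contiguous blocks with exponential lengths (mean
  1 h) until a target fraction (default 0.25) is reached — matching data
  loss from charging and non-wear, which arrives in intervals, not isolated
  points. The final block is truncated at the target, so realized and
  configured rates agree. A uniform-at-random mode exists for tests only;
* a paired "ECG-like" ground-truth sensor: the same truth curves with 1 bpm
  noise, no artifacts, independent light missingness (5%);
* defaults: 15 days per subject at 1-minute resolution. Two weeks is the
  collection span the method targets, and the 0.25 missing rate sits inside
  the range observed in that kind of deployment. One-minute sampling (not
  the 1-second native device rate) keeps a full benchmark run at desk
  scale; the resolution is configurable.
* all mechanisms draw from independent child streams of one seed, so
  toggling artifacts does not perturb noise or missingness (tested).

What passing tests on this generator do **not** show: robustness to
heteroscedastic or autocorrelated noise, circadian phase shifts, sensor
drift, or artifact distributions unlike the symmetric-shock model — real
wearable data can contain all four.

## Benchmark protocol

Leave-one-day-out per subject: the baseline is fit on all other days, the
posterior is calibrated with the test day's *noisy* sensor data, and all
five methods are scored against the ground-truth sensor. Alignment of
irregular noisy samples to test timestamps is nearest-neighbour with a 5-min
maximum gap; unmatched test points are dropped from **all** methods, so every
method is scored on the identical point set. The population mean (B) pools
historical observations with equal weight per observation (a per-subject
weighting is available via `population_weighting`). Error SD uses divisor
n−1. Multiple test days per subject contribute pooled errors, and the
"Overall" row pools errors across subjects.

## Problem sizes

The shipped validation suite uses: 100 random instances for posterior–oracle
agreement; 500 Monte-Carlo replicates (M=20 days, N=100/day) for estimator
unbiasedness; 50 designs for hat-matrix algebra; 20 calibrations on a
1-minute grid for contraction; 100 replicates per setting for consistency
(M ∈ {10, 50, 200}, N ∈ {5, 20, 100}); and 50 synthetic subjects at default
generator settings for the method-ordering benchmark (20 subjects in
`scripts/acceptance.py`). These sizes were chosen so the full suite runs on
a laptop-class single core in a few minutes while leaving Monte-Carlo
standard errors well below the effects being checked.

## Known limitations

* A single scalar `sigma^2` per subject; no time-of-day heteroscedasticity.
* Calibration is day-by-day; no sequential multi-day recursion and no
  within-day online updating.
* Baselines are strictly per-subject; no hierarchical pooling across
  subjects (the cohort-level point is precisely that subjects differ).
* Only B-splines ship, though the basis interface admits other systems.
* The 3σ band covers the latent curve by default; pass `include_noise=True`
  for a band on raw observations. Whether a published band of this kind
  should include measurement noise is genuinely ambiguous; both are exposed.
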