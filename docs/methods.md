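# Methods

## Copula directional dependence

For two series observed over the same scans, `cddnet` works on the copula
scale: each series is mapped through its empirical distribution function,
`u_t = (rank(x_t) - 0.5) / n`, which makes the margins uniform on (0, 1)
and renders everything downstream invariant to monotone transforms of the
raw signals.  The directional dependence from `U` to `V` is

    rho2_{U->V} = Var( r_{V|U}(U) ) / Var(V),      Var(V) = 1/12,

the share of `V`'s (uniform) variance explained by the copula regression
function `r_{V|U}(u) = E[V | U = u]`.  Under independence the regression
function is constant 1/2 and the index is zero; it reaches one when `V` is
a deterministic monotone function of `U`.  The difference
`delta = rho2_{U->V} - rho2_{V->U}` is the direction statistic: its sign
says which conditioning direction carries more predictive power.

The regression function is modeled parametrically by a beta regression:
`V_t | U_t = u_t ~ Beta(mu_t * kappa, (1 - mu_t) * kappa)` with
`logit(mu_t) = beta0 + beta1 u_t` and constant precision `kappa > 0`,
fitted by maximum likelihood.  The sample version of the index is the
variance of the fitted means divided by 1/12.  The theoretical constant
1/12 is used rather than the sample variance of `v`: with the
`(rank - 0.5)/n` transform the sample variance is `1/12 * (1 - 1/n^2)`,
so the constant removes an `n`-dependent factor.

Notes on the estimator:

* The logit-linear mean is an approximation to the true copula regression
  function.  For a Gaussian copula with correlation `r` the exact index is
  `(6/pi) asin(c^2/(1+c^2))` with `c = r/sqrt(2-r^2)`; the beta-regression
  estimate tracks this closed form to about 0.01 at `r = 0.42` and the
  approximation error grows with `r` (about 0.026 at `r = 0.6`).  The test
  suite checks the closed form in the moderate-dependence regime where the
  method is used.
* `rho2` is clipped into [0, 1]; excursions above 1e-6 are logged.
* PIT convention `(r - 0.5)/n` (average ranks for ties) makes the sample
  mean exactly 1/2; the alternative `r/(n+1)` differs by O(1/n) and is not
  exposed as an option.

## Serial correlation

fMRI series are strongly autocorrelated and a marginal beta regression
ignores this.  The optional `serial="ar1"` fit couples the per-observation
beta CDF values through a Gaussian copula with AR(1) correlation
(a marginal regression model in the Guolo-Varin spirit): with
`z_t = Phi^{-1}(F_beta(v_t; mu_t, kappa))`, the joint log-likelihood adds

    -1/2 sum_t (z_t - phi z_{t-1})^2 / (1 - phi^2) + 1/2 sum_t z_t^2
    - (n-1)/2 log(1 - phi^2).

The correction changes the likelihood and standard errors, but leaves the
fitted mean curve - and hence the directional-dependence point estimate -
nearly unchanged, which is why `serial="none"` is the default and is used
in every closed-form cross-check.  The AR order is fixed at 1, the minimal
model that captures scan-to-scan autocorrelation; higher-order ARMA
structures are out of scope.

Optimization: the marginal model is fitted through `statsmodels`'
`BetaModel` (precision on the log scale) started from a linear fit of
`logit(v)` on `u` plus a method-of-moments precision, polished with Newton
steps until the score vanishes (max |score|/n below 1e-7), with up to five
jittered restarts.  The AR(1) model adds `arctanh(phi)` as a fourth
unconstrained coordinate and is maximized with L-BFGS-B; standard errors
come from the numerical Hessian at the optimum.

## Direction significance

The direction of a connection is inferred from the sign of `delta` and its
uncertainty from an ordinary nonparametric bootstrap: cases `(x_i, y_i)`
are resampled with replacement (B = 100 by default), the probability
integral transform is re-applied inside every replicate so each replicate
is a valid copula sample, and `delta` is recomputed.  Reported quantities:

* basic bootstrap 95% CI `[2 d - q_.975, 2 d - q_.025]`, with type-6
  (Weibull) quantiles of the replicates - the usual resampling convention,
  slightly wider in the tails than interpolated type 7 at B = 100;
* bias `mean(d*) - d`; SD with the B-1 denominator; RMSE
  `sqrt(mean((d* - d)^2))` with the B denominator, so
  `rmse^2 = bias^2 + sd^2 (B-1)/B` holds exactly;
* a two-sided normal-approximation p-value `2 Phi(-|d|/sd)`.  The p-value
  construction is a documented assumption: it is the simplest choice
  consistent with B = 100.

At series lengths around a few hundred scans the basic interval
undercovers slightly (measured ~90-93% at n = 500, ~85% at n = 250 for a
symmetric copula); this is a known small-sample property of the basic
bootstrap, not corrected for.

## Network pruning by local FDR

All directed dependences of a region set are Fisher z-transformed,
`z = atanh(rho2)` (the transform is applied to `rho2` itself, following
the method's published description literally), and modeled as a two-group
mixture `f(z) = eta f0(z; sigma) + (1 - eta) fA(z)` with a half-normal
null (the scores are nonnegative).  Fitting steps:

1. `sigma` by censored maximum likelihood on the scores below the 75th
   percentile, treating them as a half-normal truncated at the cutoff;
   the cutoff is then moved once to `2.5 sigma` (about 99% of null mass)
   and `sigma` refitted.
2. `eta = min(1, F_n(cutoff) / F0(cutoff; sigma))` - the observed mass
   below the cutoff attributed to the null.
3. The mixture density `f` by the Grenander estimator (the slope of the
   least concave majorant of the empirical CDF on [0, inf)), which is the
   natural monotone estimator for scores that pile up near zero; below 50
   scores a reflected Gaussian kernel estimate is used instead.  Exactly
   tied scores (zero-width steps) get a large finite density, so planted
   identical effects are never diluted.
4. `fdr(z) = min(1, eta f0(z)/f(z))`, regularized to be non-increasing in
   `z` by a running maximum taken from the largest score downward.  The
   regularization only raises scores, so it can prune an edge that raw
   wiggle would have kept but never the reverse (conservative direction).

Edges with `fdr >= 0.2` are removed.  One mixture is fitted per dependence
matrix (per participant in a group study), matching the published
per-subject usage.  Measured behavior on 182-score sets: on pure nulls the
mean fraction of edges passing 0.2 is ~0.002; ten planted edges at
`rho2 = 0.4` among 172 nulls are recovered 10/10 with at most one false
edge.

For each retained unordered pair the direction with the larger dependence
is flagged dominant, and marked significant when the pair's basic
bootstrap CI for `delta` excludes zero - the bold-lower-bound convention
of the method's subject-level tables, deliberately not a second FDR pass.

## Simulators

### Asymmetric copula and BOLD measurement model

The validation copula is the Durante-style product of two Plackett copulas
with powered arguments,

    C(u,v) = A_theta1(u^alpha, v^beta) * A_theta2(u^(1-alpha), v^(1-beta)),

asymmetric whenever `alpha != beta`.  Defaults follow the validation
study: `theta1 = 5000`, `theta2 = 5`, `alpha = 1 - beta`, `beta` in
0.1-0.5.  The Plackett closed form is replaced by its independence limit
`uv` when `|theta - 1| < 1e-8` (the formula divides by `theta - 1`).
Sampling uses the conditional-distribution method: the conditional CDF
`dC/du` is evaluated by central finite differences (step 1e-6, clipped to
[0, 1]) and inverted by bisection to 1e-9; Eq-level conditionals of this
copula have no tractable inverse, and the numeric inversion is testable
against the CDF itself (the test suite compares the empirical CDF of
draws to the analytic copula on a grid).

The BOLD measurement model maps a latent pair on a fine grid (step
`a = 0.1` s) through `Phi^{-1}` (standard normal margins), convolves with
a Gaussian HRF kernel (`sigma = FWHM / (2 sqrt(2 ln 2))`, FWHM 4 s,
truncated at 4 sigma, weights normalized to sum one, reflection padding at
the edges), and keeps every `TR/a`-th sample (TR 2 s).  A duration of `T`
minutes gives `60 T / a` latent points and `60 T / TR` scans.  Kernel
normalization and padding are unspecified in the source description;
sum-one weights preserve constants and reflection padding avoids onset
transients.

### Subsampled VAR

The direction-reversal example is a three-region VAR(1)
`y_t = A y_{t-1} + e_t` with cyclic coefficient matrix (0.5 at positions
(1,2), (2,3), (3,1)), simulated from a zero state with a 1000-step burn-in
and then subsampled 1-in-L (default L = 5, n = 10000).  The subsampled
path is again a VAR(1) with coefficient `A^L`, whose nonzeros sit at the
transposed positions - every lag-based influence reverses, which is the
point of the example.  Three noise models: independent N(0,1); bivariate
normal with correlation 0.56 on the first two components; and the
asymmetric copula on the first two components.  In the asymmetric model
the copula pair is standardized (centered at 1/2, scaled by sqrt(12)) so
that all three noise components have unit variance; leaving the pair on
its raw uniform scale would let the unit-variance third component dominate
the mixing and destroy the published correlation structure (measured
cor(y1,y2) 0.20 instead of 0.42).  Mapping the copula margins to standard
normal scores instead of rescaling gives statistically indistinguishable
results; the linear rescaling is the default.

What the simulators do not emulate: scanner drift, motion, physiological
noise, nonlinear (balloon-model) hemodynamics, spatial structure.  Passing
the validation suite therefore shows that the estimator recovers
directional asymmetry injected at the noise level under realistic sampling
rates - not that it is robust to real fMRI artifacts.

## Group statistics

Degree and dependence outcomes across participants are skewed and heavily
tied, so group comparisons are nonparametric:

* Kruskal-Wallis rank-sum test with tie correction (chi-square reference).
* Quantile ANOVA: Harrell-Davis estimates of a quantile (default the
  median) per group; the observed statistic is the size-weighted
  dispersion of group quantiles around their weighted mean, and the null
  distribution comes from within-group resampling with each bootstrap
  quantile centered at its observed value (B = 2000 by default).
  Measured type-I error at nominal 5%: 0.03 over 200 null simulations
  with three groups of 30.
* Robust two-way ANOVA on cell medians: McKean-Schrader squared standard
  errors per cell, Johansen-type quadratic forms for row, column and
  interaction contrasts, referred to chi-square nulls with (J-1), (K-1)
  and (J-1)(K-1) degrees of freedom.  Measured type-I error: 0.025-0.035
  per effect at cell size 20.
* Pearson chi-square independence test for the design table.

No multiple-comparison correction is applied by default - every p-value is
reported, mirroring the method's published presentation - and an optional
Benjamini-Hochberg adjustment is available in the batch runner.

## Problem sizes used in the test and acceptance runs

Simulation-heavy checks are run at the study's stated protocol sizes where
those are small (VAR n = 10000 with 1-in-5 subsampling; copula draws of
10000; BOLD durations 10-30 min at TR 2 s; bootstrap B = 100) and averaged
over 3-5 replicate simulations where a single draw's Monte-Carlo noise
would dominate the comparison.  Calibration checks use 200 null
simulations with bootstrap B = 600 inside the quantile ANOVA.  The basic
bootstrap coverage check uses 100 datasets of length 500 at B = 100.

## Known limitations

* The beta-regression mean is logit-linear in `u`; strongly nonlinear
  copula regression functions (and very strong dependence) bias the index.
* The AR(1) serial correction assumes a single geometric autocorrelation
  scale.
* The local FDR fit needs at least ~20 directed scores (5 regions);
  the Grenander branch engages at 50.
* Bootstrap p-values use a normal approximation; with B = 100 the extreme
  tail is not resolvable.
* ROI extraction maps MNI millimeter coordinates to the nearest voxel
  through the image affine with no interpolation, and refuses overlapping
  or out-of-volume cubes rather than shrinking them.
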