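# Methods

This note documents the statistical models, numerical choices and known
limitations behind `fdagof`. Everything stated here about behavior is
computed by the test suite or by `scripts/acceptance.py`; nothing is quoted
from external runs.

## Data model

Data are records `(t_ij, Y_ij)` for subjects `i = 1..n` with `m_i`
observations each, on a closed domain `T = [a, b]`:

    Y_ij = mu(t_ij) + X_i(t_ij) + eps_ij,

with smooth mean `mu`, mean-zero Gaussian process `X_i` with smooth
covariance `G(t, t')`, and iid `N(0, sigma^2)` measurement noise. Designs
may be irregular: time vectors differ between subjects, need not be sorted,
and ties are allowed (the pair regression below excludes only same-index
pairs, not tied times). All operations are invariant to subject order and
to within-subject observation order; containers preserve input order and
never sort.

The domain defaults to the observed time range when reading data from CSV;
the simulation module always sets it explicitly to `[-1, 1]`.

## Mean estimation

`mu` is estimated on the pooled scatter by penalized cubic regression
splines: clamped B-spline basis (dimension `mean.basis_dim`, default 10,
equally spaced interior knots) with an integrated-squared-second-derivative
penalty. This penalty's null space is exactly the linear functions, so
constants and straight lines are reproduced without bias and infinite
smoothing recovers the pooled OLS line. One-dimensional thin-plate and
penalized cubic splines are practically equivalent smoothers; the cubic
B-spline form is used because the same basis machinery serves the
covariance smoother.

The smoothing parameter is selected by REML (default) or GCV. Both criteria
are evaluated through a Demmler–Reinsch decomposition computed once per set
of time points, so refitting new responses on the same design — the
bootstrap's inner loop — costs `O(N * basis_dim)` per candidate `lam`. The
search is a coarse grid on `log lam` in `[-8, 14]` refined by bounded
scalar minimization. The basis dimension for the mean is a pragmatic
default, configurable; pooled fits are insensitive to it in the smooth
regimes tested.

## Parametric null covariance

The primary family is the quadratic polynomial
`G0(t,t') = sigma0^2 + sigma01 (t+t') + sigma1^2 t t'`, the covariance of a
linear random intercept+slope model. On de-meaned data the subject marginal
is `N(0, Z_i V0 Z_i' + sigma^2 I)` with `Z_i = [1, t_i]`, and `(V0, sigma^2)`
maximize the marginal log-likelihood (reported without the `2 pi` constant;
with no fixed effects the ML and restricted likelihoods coincide, since the
data are pre-demeaned).

Numerics: `V0` is parameterized by its log-Cholesky factor and `sigma^2` on
the log scale, so the search is unconstrained while `V0 >= 0` and
`sigma^2 > 0` hold by construction. The likelihood and its exact analytic
gradient are evaluated through the Woodbury identity on per-subject 2x2
sufficient statistics `(Z'Z, Z'y, y'y, m_i)` — one objective evaluation is a
handful of vectorized small-matrix operations regardless of `m_i`.
Optimization is L-BFGS-B (`ftol` 1e-8, max 500 iterations) from two starts: a
method-of-moments fit (cross-product regression on `(1, t+t', t t')`,
PSD-projected) and an identity-scaled start; the better optimum is kept and
non-convergence is flagged, not raised. Datasets in which every subject has
a single observation are rejected: `sigma0^2` and `sigma^2` are then
confounded.

A stationary squared-exponential family
`G0(t,t') = theta * exp(-(t-t')^2 / delta^2)` is fitted by the same generic
ML machinery over `(log theta, log delta, log sigma^2)` with dense
per-subject covariance matrices; it demonstrates the pluggable-family
mechanism (any smooth parametric covariance can be added by supplying a
`cov(t, t')` evaluator and a trajectory sampler). Only the `K = 2`,
`phi = (1, t)` random-effects structure is implemented natively; larger
random-effect bases are a straightforward extension of the same code path.

## Nonparametric covariance smoother

The alternative covariance is
`G(t,t') = sum_{h,l} theta_hl Bh(t) Bl(t')` with `H` cubic B-splines per
axis (default 10, hence 6 equally spaced interior knots on the domain).
Coefficients minimize the unpenalized least-squares criterion over all
ordered within-subject pairs `j != j'` of residual cross-products; the
diagonal `j = j'` pairs are excluded so measurement noise does not bias the
surface. Symmetry `theta_hl = theta_lh` is imposed by reparameterization
(free upper triangle with symmetrized design columns), not by averaging
after the fit. Using ordered pairs counts each unordered pair twice, which
rescales the criterion but not the minimizer. No positive-semidefiniteness
correction is applied: the test statistic does not need one, and projecting
onto the PSD cone would distort the null distribution of the statistic.

The solver accumulates the normal equations per subject —
`(B_i'B_i) (x) (B_i'B_i)` minus the same-index corrections — so the
pair-level design matrix is never materialized; cost is `O(N H^2)` memory
and `O(n H^4 + N H^2)` time, and the factorized system is reused across
bootstrap replicates (only right-hand sides change). Rank-deficient designs
fall back to minimum-norm least squares with a warning; designs with fewer
off-diagonal pairs than the `H(H+1)/2` free coefficients are rejected.

The smoothed null `K G0^` uses the identical pair set and design with
responses `G0^(t_ij, t_ij')`. Because a quadratic polynomial lies inside
the cubic tensor-product span, `K G0^` reproduces the quadratic-polynomial
null exactly (to solver tolerance); for nulls outside the span the shared
smoothing bias cancels in the difference.

Measurement noise is estimated from the covariance diagonal: the mean of
`Ytilde_ij^2 - GA^(t_ij, t_ij)` over observations in the middle 50% of the
domain (`[a + 0.25(b-a), a + 0.75(b-a)]`), where the smoother's boundary
bias is smallest. The mean is floored at zero — the estimator must feed a
noise generator, and the flooring choice matters only in near-noiseless
data.

## Test statistic and bootstrap

`Tn = ∫∫ (GA^ - K G0^)^2 dt dt'` — the squared-integral form, no square
root. Both surfaces share one spline span, so the integral equals
`q' (M (x) M) q` for the vectorized coefficient difference `q` and the
basis Gram matrix `M`, which is computed exactly by per-knot-interval
Gauss–Legendre quadrature of polynomial-exact order. A grid-quadrature
oracle is kept in the test suite; trapezoid quadrature converges to the
closed form at its theoretical `O(h^2)` rate.

The null distribution is approximated by a wild (parametric) bootstrap. Per
replicate: trajectories are drawn from the fitted null at the *original*
time points, noise is added with the diagonal-based variance estimated
under the alternative model (not the null ML variance — the alternative
estimator remains valid whether or not the null holds; both are reported),
the mean is re-estimated on the bootstrap data with the same settings, both
covariances are refitted, and the statistic recomputed.

`p = L^{-1} sum I(Tn^(l) > Tn)`: strict inequality, no continuity
correction, so `p` can be exactly 0. A replicate whose component fits fail
is retried once on a fresh random substream and then dropped; the p-value
denominator is the count of successful replicates and the failure count is
reported (failures are rare; none occur in the shipped test runs). The
default `L = 1000` matches the full-scale study convention; reduced `L` is
used throughout the desk-scale experiments.

Seeding: one master seed spawns independent substreams per replicate (two
per replicate, to keep the retry stream independent), so results are
reproducible and independent of execution order.

## Direct (RLRT) competitor

When the alternative is the nested quadratic random-effects model
(`X_i(t) = b0_i + b1_i t + b2_i t^2`, `b2` independent of `(b0, b1)`),
testing the null is testing `Var(b2) = sigma2^2 = 0` — a boundary
hypothesis for which the chi-squared calibration fails. The alternative is
fitted by the same Woodbury/log-Cholesky machinery (3x3 blocks, block
constraint built into the factor); a start at the fitted null with
near-zero quadratic variance guarantees the likelihood ordering of nested
models, and `RLRT = 2 (l_alt - l_null)` is floored at 0. Estimates of
`sigma2^2` at the numerical lower bound are reported as exact zeros
(boundary estimates are valid outcomes and common under the null).

The finite-sample reference distribution is obtained by parametric
simulation — generate de-meaned data from the fitted null at the original
design points, refit both models, collect the statistics — rather than by a
spectral/pseudolikelihood algorithm; the target distribution is the same
and the cost is acceptable at desk scale (default 2000 draws). The
asymptotic `0.5 chi2_0 + 0.5 chi2_1` mixture p-value is provided as a
fallback and agrees with the simulated reference on dense balanced designs;
in small or sparse designs the simulated reference is preferred because the
point mass at zero exceeds one half. Reference draws are compared with
strict exceedance, consistent with the bootstrap test.

Within a size/power study, the reference distribution is simulated once per
cell (from the null fitted to the cell's first replicate) and shared across
replicates: all replicates share one generating design, and the RLRT null
law depends on the design rather than on the replicate. Per-dataset
simulation remains the default outside studies.

## Synthetic data generator

The generator emulates the standard study conditions:
`Y_ij = X_i(t_ij) + eps_ij` (zero mean),
`X_i(t) = b0_i + b1_i t + Delta * z_i(t)`, with unit random-effect
variances, `Cov(b0, b1) = -0.5`, unit noise variance, and a grid of 80
equally spaced points (endpoints included, `linspace(-1, 1, 80)`) from
which each subject's `m` points are sampled uniformly without replacement
(`m = 80` uses the full grid). Deviations: quadratic `z_i(t) = b2_i t^2`
with `b2_i ~ N(0,1)`, or trigonometric
`z_i(t) = xi_1 sin(2 pi t) + xi_2 sin(4 pi t)` with unit score variances.
Under `Delta = 0` the covariance of `X` is exactly
`1 - 0.5 (t + t') + t t'`.

Departures are summarized by the scale-free deviation size
`Delta^2 ∫ Var{z(t)} / Var{X(t)} dt` (denominator includes the deviation),
computed by composite Simpson quadrature on 2001 points — the integrand is
smooth and the rule is verified against a dense trapezoid oracle.

What the generator does *not* emulate: non-Gaussian processes or noise,
covariate-dependent means, informative observation times, or real-data
designs (growth curves, CD4-style sparse panels). Passing tests therefore
certify the machinery under Gaussian, correctly specified conditions; they
do not establish robustness to heavy tails or non-ignorable sampling.

## Simulation studies and problem sizes

Studies run per-cell, per-replicate with seeds derived from
`(master_seed, cell, replicate)`, so results are bit-identical for a fixed
master seed regardless of the worker count (`joblib` parallelism optional).
Every rejection rate carries its binomial Monte-Carlo standard error
`sqrt(r (1-r) / R)`.

The shipped experiments are desk-scale choices: size of the bootstrap test
at `(n=100, m=10)` with `R=100` datasets and `L=100` bootstrap samples;
size of the direct test at `(n=100, m=80)` with `R=1000` datasets and a
2000-draw shared reference; power under the trigonometric deviation at
`(n=100, m=20)` with `R=40` and `Delta in {0.6, 1.5}`, plus `n=300` for the
sample-size ordering. Full-scale runs (5000 datasets, `L=1000`) are
supported by the same code paths — only the configuration numbers change —
and the analytic standard errors for that scale (0.003 at the 5% level,
0.004 at 10%) are reproduced by the formula above.

At these reduced scales the Monte-Carlo bands are wide: size checks use
3-binomial-SE bands around the full-scale reference values, power checks
assert orderings with 2-SE slack rather than point values.

## Known limitations

* The bootstrap test is computationally heavy (a full refit pipeline per
  replicate); the engine amortizes every time-point-dependent structure,
  but `L = 1000` on dense designs remains a minutes-scale computation.
* Unpenalized spline smoothing relies on a modest `H`; highly wiggly
  covariances need larger `H` (configurable), at the cost of variance and
  of requiring more within-subject pairs.
* The p-value can be exactly zero; with small `L` its resolution is `1/L`.
* The mixture-chi-squared fallback for the direct test is anticonservative
  or conservative depending on the design; it is a convenience, not the
  calibrated reference.
* Only Gaussian processes and noise are modeled; the likelihoods, the
  bootstrap and the RLRT all assume Gaussianity.
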