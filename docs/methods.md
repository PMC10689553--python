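# Methods

## The model

`mltscan` screens a metabolome (p metabolite columns, one sample table) for
association with a single continuous variable of interest X (an age-like
exposure throughout the documentation).  Each metabolite Y_i is modelled by a
*transformation model*

    P(Y_i <= y | x) = F_eps( h_i(y) - x' beta_i ),

where h_i is a strictly monotone, metabolite-specific baseline transformation
estimated from the data jointly with beta_i by maximum likelihood ("most
likely transformation").  F_eps is the standard normal CDF by default
(probit link; beta_i is then a shift on a standardized latent scale, which is
what makes effects comparable across arbitrarily scaled metabolites), or the
standard logistic CDF (continuous outcome logistic regression; beta_i is a
log-odds ratio valid at every cutoff of Y_i).

Because the dependence of a metabolite on the exposure may be linear or
log-shaped, each metabolite is fitted twice, once per *metameter* of the
exposure: the raw variable X and its natural logarithm log X.  Metameters are
deliberately left uncentered and unscaled, so effects are reported per raw
unit (per year, or per log-year).  The family of tests therefore has 2p
members, and the joint null hypothesis for metabolite i is
beta_i[arith] = beta_i[log] = 0.

## The baseline transformation

h_i is parameterized on a Bernstein polynomial basis of order M on a bounded
support (a_i, b_i):

    h_i(y) = sum_k theta_k C(M,k) z^k (1-z)^(M-k),   z = (y - a_i)/(b_i - a_i).

Non-decreasing theta gives a monotone h; for unconstrained optimization theta
is written through log-increments, theta_k = gamma_0 + sum_{j<=k} e^{gamma_j}.
Defaults:

* order `M = 6` for data analysis (`ScanConfig.order`); the simulation-based
  calibration checks run at M = 4, which keeps the same model class (the
  Bernstein family is nested in M) at a problem size suited to hundreds of
  replicate scans;
* support = observed anchor range extended by 10% on each side
  (`support_margin`); h absorbs affine changes of Y, so beta is invariant to
  the metabolite's scale (tested);
* evaluations are clamped to the support within a 1e-9 relative slack to
  tolerate float noise at the edges.

## Censoring and ties

Metabolite columns are encoded per observation before fitting:

* values at or below the limit of quantification (LOQ) are **left-censored**
  at the LOQ; their likelihood contribution is F_eps(h(loq) - x'beta).
  "At or below" uses <=, since a value reported exactly at the LOQ
  conventionally means "not quantifiable above".
* repeated identical values (**ties**, typically from limited recording
  precision) are re-encoded as **interval** observations: a tied value u is
  read as "the truth lies in (l, r]" where l and r are the midpoints toward
  the adjacent distinct observed values; the outermost tied values extend by
  half the nearest gap.  Any duplicated uncensored value counts as a tie (no
  minimum multiplicity).  The midpoint convention is this package's choice —
  it treats the recorded value as a rounding of the truth; other software
  stores ties differently, so interval endpoints are not expected to match
  other implementations digit for digit.
* missing values are kept as explicit markers; each model uses its own
  complete cases, and the joint inference handles the resulting unequal
  sample frames (below).

Exact observations contribute log f_eps(h(y) - x'beta) + log h'(y); interval
observations log(F(h(r) - x'b) - F(h(l) - x'b)), computed in log space with
an underflow floor so a pathological interval never produces -inf.

## Fitting

Each of the 2p models is fitted by Newton iterations with the analytic
gradient and analytic observed information in the (gamma, beta)
parameterization (the information includes the curvature of the
log-increment reparameterization).  The Hessian spectrum is clamped to its
absolute value with a relative floor (a saddle-free modified Newton step) and
steps are capped at 50 units per coordinate, which makes the iteration robust
on the sharp, ill-conditioned surfaces produced by heavy ties.  Columns that
resist this path fall back to bounded L-BFGS-B (log-increments bounded in
[-30, 8], gamma_0 in +-200) followed by the same Newton polish, and one
seeded random restart is attempted before a model is flagged.

Starting values: theta from a ridge-stabilized regression of the
link-transformed empirical CDF (ranks Winsorized at 1/(2n)) on the basis,
isotonized; beta = 0.

Convergence is declared when the curvature-scaled score norm
max_j |g_j| / max(1, sqrt(I_jj)) drops below 1e-3; in practice converged fits
land near machine precision (score column sums ~1e-9).  The scale-aware norm
matters because covariates on large raw scales (age in years) inflate raw
score coordinates by orders of magnitude.  Non-convergence and
non-positive-definite information are *flags*, never exceptions, so a
many-metabolite scan proceeds; flagged models are excluded from the joint
family and reported with reasons.  A heavily censored metabolite is the
expected way to hit this path: with most of the mass below the LOQ the
Bernstein coefficients are weakly identified.

## Joint inference

The 2p per-model estimates are correlated (shared samples, correlated
metabolites, near-collinear metameters).  The joint covariance of the tested
coefficients is recovered from the fitted models alone via the multiple
marginal models construction: with per-observation score contributions s_ij
and observed informations I_j,

    Cov(beta_j, beta_k) = [ I_j^{-1} (sum_i s_ij s_ik') I_k^{-1} ]_(tested, tested).

Samples missing in model j contribute zero score rows for j — the
estimating-function convention that keeps models fitted on different
complete-case subsets in one joint frame.  This differs from software that
requires a single shared sample frame for all models; with no missing data
the two conventions coincide.  Near-flat information directions go through a
Hermitian pseudo-inverse (rcond 1e-10).

Single-step max-|t| inference then computes the equicoordinate critical
value c solving P(max_j |Z_j| <= c) = level for Z ~ N(0, R), with R the
estimated correlation matrix.  Simultaneous intervals are beta_j +/- c se_j
and adjusted p-values are p_j = 1 - P(max |Z| <= |t_j|), which controls the
familywise error rate while exploiting correlation (always at least as sharp
as Bonferroni, never below the unadjusted quantile — asserted as an
invariant).  The default family spans all 2p models; `joint_family =
"per_metameter"` corrects each metameter panel separately.

The rectangle probability is a Genz-style sequential-conditioning integral
evaluated by randomized quasi-Monte Carlo: 8 scrambled-Sobol replicates of
2^14/8 points by default (seed 20230101), with the replicate spread reported
as the Monte-Carlo error and the point count doubled until the error is
below `qmc_tol` (1e-4 by default).  Points are cached per correlation matrix
so the root search and all adjusted p-values share one quadrature — this
also makes the estimate monotone along the root search.  A singular R
(duplicated tests) is handled by eigenvalue clipping plus a tiny Cholesky
jitter.  Adjusted p-values are floored at the unadjusted two-sided p and
nudged across the alpha boundary where QMC noise would otherwise let the
test and the interval disagree; significance flags are always derived from
the intervals.  Simulation-heavy checks run at 2^11 points / 4 replicates
(tolerance 5e-3), which moves critical values by well under the assertion
tolerances.

## Synthetic data

The generator emulates the data features the scan is built for, with known
ground truth.  Per metabolite:

    Z_i = beta_i * m_i(X) + eps_i,   Y_i = g_i(Z_i),

X ~ Uniform(18, 80) (an adult age range), m_i the arithmetic or logarithmic
metameter, eps block-equicorrelated standard normal (consecutive blocks,
default size 5 at rho 0.5), and g_i a strictly monotone distortion
(identity, exp, cube, or a logistic warp) standing in for heterogeneous
scales and skewness across analytical platforms.  Censoring replaces values
at or below the empirical `censor_frac` quantile by that quantile (so the
censoring rate is controlled exactly and the LOQ is known to the truth
record); rounding to `round_decimals` creates ties; a Bernoulli mask creates
missingness.  The metadata table carries the exposure (`age`) and an
independent `bmi` column with no true effect, for exercising adjustment.

Because the latent model is exactly a probit-link transformation model,
beta_i is recoverable on the latent scale whatever the distortion — this is
what the recovery checks assert.  What the generator does *not* emulate:
instrument-level spectra, batch effects, exposure-dependent censoring,
missingness that is informative, and heavy-tailed error laws.  Passing
calibration on these simulations therefore shows correctness of the
machinery under the stated model, not robustness to model violations.

Simulation problem sizes used by the calibration checks: the null
familywise-error run uses p = 20, n = 200, 500 replicate scans; the power
and recovery run uses p = 6, n = 300, 200 replicates with true effects
0.015 (arithmetic, per year) and 0.6 (logarithmic, per log-year) — both
chosen a priori by a power calculation targeting a standardized effect near
|t| ~ 4.6 against a critical value near 3, i.e. roughly 95% single-pair
power, so that "majority power" is a stable assertion under Monte-Carlo
noise.

## Known limitations

* A large fraction of values below the LOQ leaves the Bernstein coefficients
  weakly identified; such models are flagged and excluded from the family
  rather than rescued.
* Interval endpoints for ties are a convention (midpoints); effects are
  insensitive to the choice in our simulations, but endpoint-level agreement
  with other tie conventions should not be expected.
* The sandwich/mmm covariance is asymptotic; at small n with many basis
  coefficients the familywise error can drift from nominal (the calibration
  check pins it at n = 200, M = 4).
* Right-censoring and stratified baselines are out of scope.
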