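# Methods

## Setting and model

`geoblup` targets genome-wide selection in a designed cross population:
fathers and mothers produce full-sib families; a subset of offspring is
phenotyped repeatedly over time; breeding values must be predicted for
the unphenotyped offspring at a target time beyond the last measurement.
Biallelic marker calls are coded +1 / 0 / -1 (homozygote, heterozygote,
other homozygote) into the covariate matrix **Z**; both heterozygote
orders receive 0.  Distances between individuals are plain Euclidean
distances between rows of **Z**, with no allele-frequency centring or
scaling — the kernel operates on the raw codes.

### Stage 1: logistic extrapolation

Each phenotyped individual's series (t, y_it) is fitted separately with
the three-parameter logistic mean alpha/(1 + beta e^(-gamma t)) by
nonlinear least squares (`scipy.optimize.least_squares`, analytic
Jacobian evaluated in log space for stability).  Starting values are
deterministic functions of the data (alpha0 = 1.05 max y; beta0 from the
t = 0 observation; gamma0 from the log-slope between the first and last
points) plus a fixed fallback grid, so the fit is reproducible without a
seed.  With five time points each individual leaves two error degrees of
freedom; the residual variance is pooled across individuals as
sigma^2 = sum RSS / sum error df (= RSS/2n in the five-point design).
The prediction at the target time uses the delta method with the
parameter covariance fixed at sigma^2 (J'J)^-1, J the Jacobian at the
least-squares optimum.  Fixing the residual variance in this second pass
rescales standard errors only — the point predictions are the pass-one
least-squares values, a property asserted by the test suite.  The squared
standard error becomes the known within-individual error variance of the
extrapolated trait.

The three-parameter form was chosen because it leaves exactly two error
df per five-point series; the delta method is the standard behaviour of
nonlinear mixed-model software for prediction standard errors.  Both
choices are recorded in the pipeline provenance output.

### Stage 2: kernel mixed model

The extrapolated traits follow y = mu + g + v + e with
var(g) = sigma2_g * Gamma.  Gamma is Z Z' for ridge regression or
{f(d_ii')} for the spatial kernels:

| kernel      | f(d)                                              |
|-------------|---------------------------------------------------|
| linear      | (1 - theta d) for theta d <= 1, else 0            |
| quadratic   | (1 - theta d^2) for theta d^2 <= 1, else 0        |
| power       | theta^d, theta in (0, 1)                          |
| exponential | exp(-d / theta)                                   |
| gaussian    | exp(-d^2 / theta^2)                               |
| spherical   | 1 - 1.5 (d/theta) + 0.5 (d/theta)^3 for d <= theta |

`independent` omits g entirely.  Linear, quadratic and spherical Gamma
need not be positive semidefinite; they are stabilized by eigenvalue
clipping at zero (default) or uniform diagonal jitter, and the applied
correction is reported on the results object.

Residual handling follows the two options of the motivating design.
Under `pooled`, e and v both multiply the identity and are not separately
identifiable, so they form one component reported as the residual
variance sigma2_e (this is why a pooled ridge fit counts q = 2 covariance
parameters, not 3).  Under `fixed`, var(e_i) is frozen at the stage-1
squared standard errors and the free identity component is the polygenic
variance sigma2_v.  Known error variances of exactly zero are floored at
1e-10 x var(y) so the marginal covariance stays positive definite at the
sigma2_v = 0 boundary.

The extended (pedigree) model adds Omega = sigma2_f V_f + sigma2_m V_m +
sigma2_c V_c, where the indicator matrices mark shared fathers, mothers
and crosses (diagonal 1; equivalently incidence products Z_a Z_a' of
grouped random effects — the representation used to predict parent
effects for unphenotyped offspring).  Unknown parents become unique
singleton levels.  No multi-generation numerator relationship matrix is
built; the polygenic effect is independent by design because parental
pedigree depth is typically unavailable in this setting.

## REML estimation

The REML log-likelihood is

    l_R = -1/2 [ (n-p) log 2 pi + log|V| + log|X' V^-1 X| + y' P y ],

with X a column of ones (the intercept is the only fixed effect) and
P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1.  The full constant is included, so
AIC = -2 l_R + 2q is on the scale mixed-model packages print; q counts
estimated covariance parameters only (a profiled theta counts, fixed
known error variances do not).

Two inner solvers maximise over the variance components:

* **Two-component fast path** (sigma2_g Gamma + sigma2 I, no fixed R, no
  Omega): one eigendecomposition of Gamma reduces every evaluation to
  O(n).  The total variance s is profiled out in closed form and the
  variance ratio h = sigma2_g / s is optimised on the logit scale
  (grid + bounded Brent).  The logit parameterisation matters: REML
  optima of the Gaussian kernel can sit on a ridge where sigma2_g grows
  without bound at fixed sigma2_e (the kernel approaching its
  quadratic/ridge-regression limit), which corresponds to h -> 1 with the
  profiled s diverging — resolvable coordinates where (sigma2_g,
  sigma2_e) are not.  Exact h = 0 / h = 1 boundary candidates are
  evaluated directly so boundary estimates are reported as exact zeros.
* **General dense path** (fixed heterogeneous R and/or Omega): L-BFGS-B
  on non-negative variance multipliers with analytic REML gradients
  (-1/2 [tr(P V_j) - y'P V_j P y]), components preconditioned by their
  mean diagonal, three deterministic starts.  After convergence every
  negligible component (< 1e-6 relative) is subjected to an explicit zero
  test: it is pinned to zero and the rest refitted, and the zero is kept
  if the profiled log-likelihood loses less than 1e-7.  This is how null
  variance components (e.g. a mother variance in a population without
  maternal effects) surface as exact boundary zeros.

A kernel range parameter theta is profiled by an outer one-dimensional
search: a 15-point log-spaced grid refined by bounded scalar minimisation
(tolerance 1e-4 on the log range by default).  The search domain is
restricted to ranges between 0.01 x the median and 100 x the maximum
pairwise distance: below it the kernel is numerically the identity and
above it numerically its large-range quadratic limit (the entries
1 - f(d) fall below double precision), so the profile is flat beyond both
ends and a boundary optimum is reported at the bound.  Internally each
kernel is parameterised by a range-like quantity (power's theta in (0,1)
maps to exp(-1/range)) and theta is reported on its native scale.

## GEBVs

GEBVs are BLUPs of mu + g_i: mu_hat + sigma2_g Gamma_obs V^-1 (y - mu_hat)
for phenotyped individuals and mu_hat + sigma2_g Gamma_{new,obs} V^-1
(y - mu_hat) for unphenotyped ones, with the cross block built from cross
distances (spatial kernels) or Z_new Z_obs' (ridge regression).  The
polygenic BLUP v_hat is computed and exposed separately
(`polygenic_blup`) but not added to the GEBV: v absorbs residual and
non-marker variation, contributes nothing out of sample under
independence, and including it would make in-sample GEBVs collapse onto
the data whenever the free identity component dominates.  When the
pedigree model is active, predicted father/mother/cross effects are added
for every individual whose parents appear among the training levels,
whenever the corresponding variance is estimated above zero.  Under the
ridge model this BLUP coincides with the marker-effect ridge solution
u = (Z'Z + lambda^2 I)^-1 Z'(y - mu) through Z u = g_hat, with
lambda^2 = sigma2_e / sigma2_g — an identity the tests verify to
near machine precision.

Model comparison reports, per fitted model: AIC, the free
identity-variance component (residual or polygenic, depending on the
residual mode), theta, the Pearson correlation of GEBVs with the stage-1
fitted values (phenotyped set), and with true breeding values on the
unphenotyped validation set when a TBV table is available.

## Synthetic populations

The simulator emulates the structure the pipeline expects rather than any
particular real genome.  Founders draw two haplotypes per marker with
per-marker allele frequencies uniform on (0.2, 0.8); offspring arise by
Mendelian sampling, either with unlinked markers (default) or Haldane
recombination on an equally spaced linear map.  A random subset of
markers acts as additive QTL with N(0, scale^2) effects; the true
breeding value is the QTL-code weighted sum.  Phenotypes lie on logistic
curves whose asymptote is alpha_base + TBV, observed at the design times
with i.i.d. Gaussian error.

Defaults mirror the motivating study dimensions at full scale: 2 fathers
x 10 mothers x 100 offspring (~2000 offspring), 450 markers with 30 QTL,
times (0, 132, 265, 397, 530), phenotyped fraction 1000/2025, target time
600.  Growth baselines alpha = 60, beta = 9, gamma = 0.01 put the curves
at about 96% of their asymptote by the last measurement — a genuine but
mild extrapolation to t = 600 — and measurement error sd 1.0 keeps the
within-individual error variances small relative to the genetic spread,
the regime in which fixing var(e_i) barely moves the fits.

What the simulator does not emulate: dominance and epistasis (additive
architecture only; a dominance hook exists but is off by default),
genotyping error and missingness, selection or multi-generation pedigree
structure, and any specific real linkage map.  Passing tests therefore
demonstrate correctness of the machinery and the qualitative model
rankings under additive inheritance, not performance claims for any real
data set.

## Problem sizes in tests and the acceptance script

The test suite runs the statistical checks at desk scale: oracle
equivalence on 25 instances with n <= 30; parameter recovery on 20
replicates at n = 300 (3 x 5 crosses, 45 markers, Gaussian kernel with
theta at the 0.6 distance quantile, sigma2_g = 4, sigma2_v = 1 — the
design with the smallest asymptotic REML standard errors among those
examined); stage-1 calibration at n = 500 (1000 pooled df); model
comparison over 5 replicate populations of ~200 offspring; and the
boundary-rate study on 20 replicates of a 6 x 8 cross design.  The
acceptance script's main study uses 2 x 10 crosses x 30 offspring
(600 offspring, ~296 phenotyped) with 150 markers and 30 QTL.

## Numerical choices and limitations

* Convergence: inner solvers run to ftol 1e-13/1e-14; theta refinement to
  1e-4 on the log range (tightenable per call).
* Gamma stabilization: eigenvalue clipping at zero by default; the
  correction magnitude is recorded on the fit.
* BLUP back-solves retry with escalating diagonal jitter (1e-12 to 1e-8
  x var(y)) if the fitted covariance is numerically singular at a
  variance boundary.
* Variance-component uncertainty is not reported (no standard errors on
  sigma2 estimates); model comparison relies on AIC as designed.
* At n = 300 the Fisher information bounds the attainable relative
  standard error of the Gaussian-kernel variance split at roughly 30%;
  recovery checks at that size sit near this limit and say little about
  estimator quality beyond consistency and lack of bias.
* Missing genotype calls are a hard error unless mean-code imputation is
  explicitly enabled; no VCF/PLINK parsing, no LD pruning, no
  VanRaden-style centred relationship matrices, no Matern or anisotropic
  kernels, no cross-validation engine.
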