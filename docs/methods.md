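# Methods

This note records the models the package implements, the conventions and
numerical choices behind them, what the synthetic generator does and does
not emulate, and the design decisions taken where several defensible
options existed.

## Measurement model and invariance sequence

The core model is a one-factor CFA with mean structure for the seven
health-system-responsiveness (HSR) indicators, fitted per group by
normal-theory maximum likelihood on sample moments (divisor-*n*
covariances).  Identification fixes the factor mean to 0 and variance to
1 in every group at every level, so all loadings and intercepts are free
parameters that can be constrained: metric invariance imposes equal
loadings across groups, scalar invariance additionally equal intercepts.
Residual variances are always group-specific; selected residual
covariances can be added, optionally constrained equal across groups.

Conventions (also emitted in every fit's metadata, since SEM software
differs on each of them):

* discrepancy `F = sum_g (n_g/N) [log|Sigma_g| + tr(S_g Sigma_g^-1)
  - log|S_g| - p + (m_g-mu_g)' Sigma_g^-1 (m_g-mu_g)]`,
  chi-square `= (N - G) * F_min`;
* baseline model for CFI: per-group independence with free means and
  variances (closed form);
* `RMSEA = sqrt(G) * sqrt(max(chi2-df, 0) / (df*N))` (multi-group
  convention), reported as 0 with a flag when `df = 0`;
* sample-size-adjusted BIC `= -2 logL + q * ln((N+2)/24)`.

Estimation treats the 5-category ratings as continuous and uses plain ML
— no robust (scaled) chi-square corrections and no ordered-categorical
(WLSMV-type) estimation.  The calibration studies in the test suite
quantify what this costs: with 5 roughly symmetric categories the
metric/scalar likelihood-ratio tests reject a true constraint at roughly
4–8% versus the nominal 5% at n = 200/group.  Severely skewed ordinal data
would be treated less well; that is a known limitation.

Decisions follow fixed rules: configural acceptance requires CFI >= 0.95
and RMSEA <= 0.08; a constrained level is rejected if the chi-square
difference is significant at 0.05, or CFI drops by >= 0.005, or RMSEA
rises by >= 0.010 (each criterion can be switched off; the aBIC change,
with >= 6 as the conventional benchmark, is reported alongside but does
not enter the default decision).  Negative chi-square differences are
floored at zero with a flag.

Modification indices are univariate score (Lagrange-multiplier) tests:
the gradient and (numerically differentiated) Hessian of the discrepancy
at the restricted optimum give `MI = (N-G)/2 * g_c^2 / h_c`, where `h_c`
is the Schur complement of the candidate's Hessian entry, plus the
expected parameter change `-g_c / h_c`.  A rejected configural model may
be re-specified by freeing the largest-MI residual covariance (held
equal across groups), at most twice — ad-hoc modifications restrict
comparability, so the cap is deliberate.

Optimization is L-BFGS-B with analytic gradients (the matrix-calculus
derivatives of `F` with respect to every parameter block), a second
polishing pass with tighter tolerances, and, within the invariance
sequence, warm starts of each constrained level from the previous
level's solution (the better of warm and cold fits is kept).  Negative
residual-variance solutions (Heywood cases) are flagged, never
truncated.  Population-moment inversion is exact to chi-square < 1e-6
and parameter error < 1e-5 (asserted in the tests).

## Covariate models

Manifest covariates (predicted thresholds or socio-demographics) enter
as exogenous observed variables with saturated means and covariances,
regressed on the indicators (`Y = tau + Lambda eta + Gamma x + e`); no
latent variable is placed behind them, and the latent factor is kept
independent of them.  Invariance constraints continue to apply to
loadings and intercepts only; the `Gamma` paths are group-specific by
default (a configuration switch can equate them).  Because the covariate
block is saturated, the model degrees of freedom equal those of the
plain MGCFA at the same level.

## Non-parametric rescaling

For strictly ordered anchors the scalar rule applies exactly; the final
branch is `y > z_J` (the symmetric counterpart of the first branch).
When a respondent's anchors are tied or misordered, C becomes the
integer interval of all categories attainable under some resolution of
the ambiguity.  The implemented semantics: every inclusion-maximal
subset of anchors whose ratings are weakly increasing in the intended
order is a "resolution"; within a resolution, y's position on the full
1..2J+1 ladder is bounded by the retained neighbours (dropped anchors
contribute no constraint, and an equality run may extend across dropped
slots); `[Cs, Ce]` is the hull over resolutions.  Two anchors tied with
y therefore span `{2, 3, 4}`, and a brute-force enumeration oracle
verifies the construction exhaustively on the rating grid for J <= 3.
Equality between a rating and a non-integer anchor is tested within
1e-9; with pooled-mean anchors ties are impossible and only odd C values
occur.

Anchor sources: *pooled* means of the bottom/middle/top vignette ratings
over all respondents (the default), optionally per language group, or
*per-respondent* (each respondent's own ratings where fully available,
pooled fallback).  A pooled scalar anchor defines one fixed monotone
recoding for everyone — it can never produce `Cs < Ce` intervals and
cannot remove respondent- or group-level DIF; it mainly re-expresses the
scale.  Genuine DIF correction requires respondent-specific (or at least
group-specific) anchors, which is why the interval machinery and the
`per-respondent` mode exist.  The package's demonstration of the
correction (tests and acceptance script) uses a full-coverage design in
which every respondent rates bottom/middle/top for every indicator.

Ordering accuracy counts a respondent–indicator pair as accurate when
its rated vignette levels are weakly increasing in intended level
(strict ordering is a switch); proportions are reported per group and
overall.

## CHOPIT

One model per indicator.  The self-report's latent value is
`N(X_i beta + eta_i, 1)` with `eta_i ~ N(0, omega^2)`; vignette level
*j*'s latent value is `N(theta_j, sigma_j^2)` with no respondent effect;
both are discretised by the same respondent-specific thresholds
`tau^1 = gamma^1 V_i`, `tau^k = tau^{k-1} + exp(gamma^k V_i)` (response
consistency), which is what identifies `gamma`.  Identification fixes
the self residual SD to 1 and omits the intercept from `X beta`
(location and scale are absorbed by the threshold intercepts).

The random-effect integral is evaluated by Gauss–Hermite quadrature
(15 nodes by default; 15 vs 31 nodes agree to < 1e-4 per observation,
and the quadrature matches Monte-Carlo integration with 1e6 draws within
3 MC standard errors).  `omega` and the `sigma_j` are optimized on the
log scale, so invalid parameters cannot arise.  The start is
deterministic: marginal ordered-probit cutpoints for the threshold
intercepts, zeros for all slopes, vignette locations interpolated from
the mean vignette rating; an optional seeded multistart exists for rough
likelihoods.  Standard errors come from the numerically differentiated
observed information with a delta-method map back to the natural scale.
With no vignette data, a fixed `omega = 0` and intercept-only
thresholds, the estimates coincide with an ordered probit (checked
against an independent implementation in the tests).

Default covariates mirror the study design: language (group), gender,
age band and insurance card; education is excluded by default because
its missingness would shrink the estimation sample.  Fitting uses the
respondents of the full-ladder vignette sets (2–5); thresholds are then
predicted for the entire sample.  Threshold screening regresses each
indicator's self-report on each predicted threshold (per group, simple
linear path) and keeps thresholds with at least one path significant at
alpha = 0.05.

Because the per-indicator thresholds are smooth functions of a few
covariates, the screened set is often highly collinear (and, under a
DIF-free population, consists of near-constant noise).  Before the
covariate MGCFA the pipeline therefore ranks the kept thresholds by
their strongest path, greedily prunes pairs with |r| >= 0.90, caps the
set at 8, and z-scores the survivors — a pure linear reparameterization
that leaves the chi-square unchanged but keeps the saturated covariate
block numerically well conditioned.

## Synthetic generator

The generator emulates the reference study's conditions: two language
groups ("english", "arabic") with default analysis sizes 145/91
(configurable, e.g. 183/121 for the full sample), seven indicators
loading on one factor, 5-category ratings (1 = very bad ... 5 = very
good, "cannot say" treated as missing), five randomly assigned vignette
sets (set 1: bottom/middle/top for all seven indicators; sets 2–5: the
full five-vignette ladder for attention+respect, communication+
amenities, confidentiality+choice, autonomy), and socio-demographic
marginals matching the published sample description (23% female, five
ordered age bands at 46/19/15/9/11%, education at 31/25/44% with 12%
missingness, 40% insurance-card holders).  Age uses five bands — the
published table lists four plus an implicit youngest reference band.

Default truth: loadings 0.55–0.75 with intercepts around 3.6–4.2 on the
raw scale; residual SDs equal to the loadings, giving standardized
loadings of ~0.71 and a latent composite reliability of ~0.87 (matching
the instrument's reported reliability; the observed ordinal omega is
~0.84 after discretization).  Thresholds default to 1.5/2.5/3.5/4.5 with
all covariate effects zero — a scalar-invariant, DIF-free population.
Vignette locations sit at 1..5 with latent SD 1.0, which yields ordering
accuracy around 0.7, in the vicinity of the reference survey's 68%/76%.
A respondent-level random effect (`omega`, default 0) can induce shared
variance beyond the factor.

Vignette ratings are discretised through the *same* respondent
thresholds as the self-reports, so response consistency holds by
construction.  `inject_noninvariance` shifts a single loading,
intercept, or threshold-coefficient row in one group, leaving everything
else bit-identical — the lever for calibration and power studies.

What the generator does not emulate: the clustered (room/facility)
sampling structure, item-level "cannot say" behaviour that differs from
random missingness, non-normal latent distributions, and vignette
inequivalence (all respondents share the same `theta_j`).  Passing tests
therefore certify the statistical machinery under the stated model, not
robustness to those real-data complications.

## Study sizes used in the checks

Simulation-based checks run at sizes chosen to make their Monte-Carlo
error small relative to the asserted margins: LRT calibration with 500
replicates at n = 200/group, power for a 0.4 loading shift with 200
replicates at the study's unbalanced 145/91, CHOPIT recovery at
n = 2000 with 20 replicates, generator-level calibration with 100
surveys at n = 500/group, and the RC-DIF contrast with 40 replicates at
145/91.  The acceptance script uses reduced replicate counts for the
slower blocks (20 DIF replicates, 5 recovery replicates) and reports
each problem size alongside the value.

## Known limitations

* Plain ML on ordinal data (above); no FIML — missing data are handled
  by listwise deletion per analysis, mirroring the shrinking per-model
  sample sizes of the reference workflow.
* The non-parametric adjustment with pooled anchors is a monotone
  recoding, not a DIF correction; interval-valued C is only informative
  with respondent-level anchors.
* CHOPIT assumes vignette equivalence; the screening step is a crude
  multiple-testing-prone filter (by design, following the reference
  procedure) and is stabilised here by collinearity pruning.
* Modification-index search is capped at two additions and limited to
  residual covariances.
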