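# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `fbstev`, at the level of detail a maintainer or a
careful user needs. Everything quantitative stated here is recomputed by the
test suite or by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## 1. Setting

A parametric model f(y; θ), θ = (ψ, λ) ∈ Θ ⊆ ℝᵈ with scalar interest ψ and
nuisance λ. Likelihood quantities used throughout:

* profile log-likelihood ℓp(ψ) = ℓ(ψ, λ̂ψ), with λ̂ψ the constrained MLE;
* profile score ℓp′(ψ), computed through the envelope identity as the
  ψ-component of the full score at (ψ, λ̂ψ);
* profile observed information jp(ψ), by nuisance-block reduction
  jψψ − jψλ jλλ⁻¹ jλψ of the observed information at (ψ, λ̂ψ).

The FBST e-value for H0: ψ = ψ0 is one minus the mass of the tangential set
(the region where the posterior surprise exceeds its value at ψ0); small
values are evidence against H0. Under H0 the e-value is asymptotically
distributed as V(c) = Q(d−h, Q⁻¹(d, c)) with Q the chi-square CDF; for a
scalar full parameter (d = 1, h = 0) this is the identity, i.e. the e-value
is asymptotically uniform.

## 2. Median matching prior and pseudo-posterior

The pseudo-posterior for ψ is log π*(ψ|y) = ℓp(ψ) + ∫ m(ψ, λ̂ψ) dψ, where m
is the median modification of the (profile) score:

* scalar θ: m = κ3/(6 κ2), with κ2 = i(θ) and κ3 = E(ℓθ³);
* profile: m = −κ1 + κ3/(6 κ2), with κ1, κ2, κ3 the cumulants of ℓp′(ψ).

Two conventions had to be fixed where sources render them inconsistently:

**Sign.** We use the sign under which, for a canonical exponential family,
the modified score is ℓθ + Kθθθ/(6 Kθθ), so the exponential-rate estimator
is θ̃ = (n − 1/3)/(n ȳ) and the median matching prior is i(θ)^{1/6}. This
direction is certified by simulation: P(θ̃ ≤ θ0) ≈ 1/2 (the
median-unbiasedness test), whereas the opposite sign pushes the probability
away from 1/2. The Firth adjustment mF = (κ3 + E(ℓθθ ℓθ))/(2 κ2) is signed
the same way; it reproduces the Jeffreys penalty i^{1/2} in canonical
families and the exactly mean-unbiased (n−1)/(n ȳ) exponential-rate
estimator. The opposite convention remains available as
`sign_convention="as-displayed"` for audit.

**Grouping.** The profile adjustment is −κ1 + κ3/(6κ2), not
−(κ1 + κ3)/(6κ2): only the former reduces to the scalar case at κ1 = 0 and
equals "score minus its Cornish–Fisher median" (median(X) ≈ κ1 − κ3/(6κ2)).

**Scale-model exponent.** Direct computation for the exponential scale
model gives m = +1/(3θ), hence prior ∝ θ^{1/3}; this is the form consistent
with the median-unbiasedness simulation and is what the package implements
and tests.

## 3. Invariance: what is exact and how it is achieved

Because m transforms as m_φ = (dθ/dφ)·m_θ under a monotone interest
reparameterization φ = g(ψ), the pseudo-posterior transforms by
*composition* — log π*_φ(φ|y) = log π*_θ(g⁻¹(φ)|y) + const — with no
Jacobian term. That is precisely why the MAP is equivariant (it solves the
equivariant estimating equation), but it also means that plain density-mass
tangential sets and HPD contents would only be invariant asymptotically.

To make e-values and HPD probability contents exactly invariant, the
package keeps π* as the surprise function (so tangential and HPD sets are
superlevel sets of π*, which map through g exactly) and measures their mass
under the **information measure** √jp(ψ) dψ, which is itself
parameterization-invariant (√jp picks up exactly the Jacobian). This is the
classical invariant-FBST construction with the Jeffreys density in the role
of reference measure, absorbed into the computation rather than elicited by
the user. For location models the information is constant and the weighted
mass coincides with the plain one, so all symmetric closed-form reductions
(e.g. ev = 2(1 − Φ(z)) for a normal posterior) are unchanged.

`evalue_exact_1d` and `hpd_interval` take the weight explicitly (default:
flat, appropriate for raw densities such as ABC/KDE output); the model-based
dispatcher and the CLI pass the information weight automatically. The
equivariance suite checks estimates, e-values and HPD endpoints through
log and reciprocal maps (exponential models) and arcsinh (skew-normal,
whose shape parameter spans all of ℝ) at tolerance 1e-5; hypothesis points
adjacent to the posterior mode are avoided in those checks because the
superlevel boundary of a quadratic peak is ill-conditioned at any grid
resolution.

## 4. Numerical design

**Grids.** Pseudo-posteriors live on an 801-point grid spanning the
centering estimate ± 8 SE (SE from jp), auto-doubling the half-width while
more than 1e-4 of mass sits in the outermost cells. The centering point is
the MLE when it exists; under monotone likelihood it is the
median-bias-reduced root (scalar models) or the Jeffreys-penalized fit
(logistic regression), since no gradient criterion can distinguish a
drifting optimizer from a converged one — monotonicity is detected first by
sign-checking the (profile) score over an expanding bracket.

**Correction interpolation.** m(ψ) is evaluated on a coarse subgrid (61
points for closed-form/quadrature scalar adjustments; 41 for Monte-Carlo
profile adjustments, per the correction cache below) and interpolated —
cubic spline on unbounded supports (O(h⁴)), monotone PCHIP near finite
support boundaries where m can be steep (e.g. 1/(3θ)) and a natural spline
would ring. The log-prior is the interpolant's antiderivative; its constant
is immaterial after normalization.

**Profile cumulants.** κ1ψ, κ2ψ, κ3ψ default to a parametric bootstrap at
(ψ, λ̂ψ): simulate R datasets with the observed covariate structure,
recompute ℓp′(ψ) on each (own inner optimization, warm-started), and take
k-statistics (unbiased cumulant estimators) with grouped-jackknife standard
errors. The library default is R = 20 000; the test suite and the worked
examples use R in the hundreds-to-thousands, which is adequate because m is
O(1) and enters the estimate at second order. Closed forms short-circuit
the bootstrap for canonical families without nuisance parameters. Because
the bootstrap is seeded per grid point, rebuilding a cache with the same
seed and grid reproduces it exactly.

**Correction cache.** With nuisance parameters, m(ψ, λ̂ψ) is evaluated on a
41-point grid spanning the centering estimate ± 6 SE and cubically
interpolated inside root searches and posterior builds; grid points where
the bootstrap degenerates (e.g. a separated stratum saturates, making the
profile score constant) are dropped, and the interpolant is clamped to the
surviving range.

**Inner optimization.** Constrained nuisance maximization is warm-started
Newton with step-halving on the analytic observed information, falling back
to L-BFGS-B with analytic gradients; convergence demands a gradient norm
below 1e-6 relative. Closed-form constrained MLEs (normal mean/variance)
bypass optimization.

**Root finding.** Modified-score equations are solved by two-sided bracket
expansion (doubling steps on unbounded sides, geometric approach to finite
boundaries, backing off where model quantities over/underflow) followed by
Brent's method at tolerance 1e-12. Absence of a sign change raises a
divergence error carrying the drift direction.

**Skew-normal quadrature.** The score expectations E[(yφ(yθ)/Φ(yθ))^k]
under 2φ(y)Φ(yθ) are computed by adaptive quadrature in log space — the
Mills ratio φ/Φ is evaluated as exp(logpdf − log_ndtr), which is stable
arbitrarily far into the lower tail — with the integration range split at 0
and at ±20/|θ|, where the integrand kinks and concentrates. Cross-checked
against closed forms at θ = 0 (2/π; odd moments vanish) and Monte Carlo at
θ = 3.

**Tail area.** rB* = rp + log(qB/rp)/rp is 0/0 at ψ̂; inside |rp| < 0.05 it
is replaced by a cubic through its values at |rp| ∈ {0.05, 0.1} on both
sides and flagged. The printed inverse-power notation in the source
formulas is read as division by the square root of the information
(z-statistics), forced by the asymptotic N(0, i) statements; in the
known-variance normal model with flat prior and reference this makes
qB = rp exactly and Φ(rB*) the exact posterior tail. The third-order
e-value brackets the equal-density point ψ0* on the far side of the
marginal-surprise mode by bisection on the log density (tolerance 1e-10),
extending the grid when ψ0* falls outside it; multimodal marginal surprise
densities are flagged and not supported on this route.

**Quadratic (Rao-score) posterior.** exp{−tp(ψ)²/(2 jp(ψ))} with jp taken
at ψ (score-statistic convention; `curvature_at="psi-hat"` freezes it at
the estimate instead). Grid points with non-positive curvature are trimmed
with a flag.

**ABC.** Rejection ABC draws from the prior (improper priors truncated to a
stated window, default [−5, 25] for the skew-normal shape), simulates a
dataset per draw, and keeps exactly round(fraction × draws) smallest
Euclidean distances between standardized summaries. The default summary is
the vector of sample deciles; the cross-prior experiment harness uses the
mean score on a 5-point θ-grid instead, because decile summaries are weakly
informative about the skew-normal shape in the θ ≈ 3–4 range. MAPs from
accepted draws use a Silverman-bandwidth Gaussian KDE refined by bounded
optimization; the KDE mode of 10⁵ standard-normal samples scatters with
standard deviation around 0.06, which bounds what single-run ABC MAPs can
resolve.

## 5. Synthetic data and what the tests do (and do not) show

All tests run on seeded synthetic data from the model zoo itself:
exponential/gamma/Poisson samples, skew-normal samples at θ0 = 3 with
n ∈ {20, …, 200} (including the all-positive configuration that makes the
flat-prior analysis improper), bivariate regression at ρ = 0.95 with n = 20,
and a quasi-separated logistic fixture shaped like the endometrial cancer
grade study (n = 79, a binary risk factor whose positive stratum contains
only positive responses, two continuous covariates). The generators draw
covariates once per dataset and bootstrap responses conditional on them,
matching the parametric-bootstrap convention for regression.

Passing tests therefore certify the *methodology under the model*: correct
derivatives and cumulants, median unbiasedness, equivariance, exactness and
higher-order accuracy of the approximations, and near-uniform null
e-values. They do not certify behavior under model misspecification,
real-data covariate structure, or the published point estimates for the
endometrial dataset — that file is not distributed here; the loader accepts
a user-supplied CSV (columns HG, NV, PI, EH) and the acceptance test
asserts the published values only when it is present.

## 6. Known limitations

* The interest parameter is scalar throughout; vector-interest extensions
  of the median modification are out of scope.
* For boundary samples (e.g. all-positive skew-normal data) the
  median-prior pseudo-posterior has a very heavy right tail (the prior
  behaves like θ^{-2/3} at large θ while the likelihood plateaus); the grid
  normalization is then effectively a truncation at the auto-expanded
  window, and reported tail quantities should be read accordingly. The MAP
  itself is finite and stable.
* Profile-cumulant bootstraps assume the inner optimization succeeds on
  almost all replicates; more than 1% failures abort the computation rather
  than silently biasing it.
* The Manifold-MCMC route for conditioning exactly on the modified profile
  equation is not implemented; the grid/quadrature path replaces it for
  scalar ψ, and the full-dimensional FBST (joint optimization plus
  d-dimensional integration) is deliberately absent — avoiding it is the
  point of the construction.
* `run_table1_experiment` reproduces a published experiment's *design*
  (sample sizes, prior menu, ABC budget), not its numbers, which came from
  unseeded single samples.
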