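# Methods

## Model

`semstd` operates entirely at the latent level.  A model is a finite
mixture of G classes; class g has weight π_g, Gaussian latent predictors
ξ_g ~ N(κ_g, Φ_g), and a structural equation

    η_g = α_g + Σ_j γ_j,g ξ_j,g + Σ_{j≤k} ω_jk,g ξ_j,g ξ_k,g + ζ_g,
    ζ_g ~ N(0, ψ_g),

with a single latent outcome and any number p ≥ 1 of predictors.  Each
unordered product term carries exactly one coefficient (no symmetric
halving), so coefficients equal those printed by common SEM software for
the single-product-term parameterization.  Three application modes share
this structure and differ only in constraints and interpretation:
`direct` (classes are subpopulations, all parameters class-specific),
`indirect` (the mixture approximates a nonnormal predictor distribution;
all structural coefficients including ψ are constrained equal across
classes — enforced at validation), and `multigroup` (observed groups,
parameters group-specific).

## Moment machinery

Within a class, the extended regressor vector x = (ξ, {ξ_jξ_k}_{j≤k}) has
closed-form moments.  The product means

    E[ξ_jξ_k] = κ_jκ_k + ϕ_jk

are distribution-free.  The covariances use the uncentered Gaussian
product-moment (Isserlis) identities:

    Cov(ξ_a, ξ_jξ_k)      = κ_jϕ_ak + κ_kϕ_aj
    Cov(ξ_jξ_k, ξ_lξ_m)   = ϕ_jlϕ_km + ϕ_jmϕ_kl
                            + κ_jκ_lϕ_km + κ_jκ_mϕ_kl + κ_kκ_lϕ_jm + κ_kκ_mϕ_jl

With all κ = 0 these collapse to the familiar centered-normal formulas
(zero linear–product covariance, ϕ_jlϕ_km + ϕ_jmϕ_kl blocks).

The mixture marginal of ξ is nonnormal, so Gaussian identities must never
be applied to the marginal moments.  Instead every required raw moment is
composed exactly from the component moments (law of total covariance):
E[f] = Σ_g π_g E_g[f], Cov(f,h) = Σ_g π_g(Cov_g + E_g[f]E_g[h]) − E[f]E[h].
This composition is exact, not a skewness/kurtosis approximation, and it
is what makes the marginal fourth moments deviate from Gaussian values
(heavier-tailed scale mixtures inflate Var(ξ²); symmetric well-separated
bimodal marginals deflate it — both directions are covered by tests).

## Implied outcome variances

Stacking b_g = (γ_g, ω_g), three denominators arise:

- **Within class**: ϕ₀₀,g = b_g' Σ_g b_g + ψ_g with Σ_g the Gaussian
  extended covariance above.
- **Mixture marginal** (`mixture_eta_variance`): the true Var(η) by the law
  of total variance over classes, Σ_g π_g(ϕ₀₀,g + κ₀,g²) − (Σ_g π_g κ₀,g)²,
  where κ₀,g = α_g + b_g'E_g[x] is the class-conditional outcome mean.  For
  shared-coefficient models this equals the quadratic form b'Σ_mix b + ψ in
  the mixture extended covariance *exactly*; the two independent code paths
  are required to agree to 1e−9 in the test suite, a strong cross-check on
  both moment modules.
- **Pooled frame for class-specific coefficients**
  (`pooled_eta_variance`): Σ_g π_g (b_g' Σ_mix b_g + ψ_g).  Each class's
  equation is referred to the pooled predictor distribution — the same
  convention the pooled coefficient formulas use — and the resulting
  implied variances are averaged with the class proportions so that all
  classes share one denominator and hence one metric.  This quantity
  deliberately differs from the marginal Var(η) when coefficients differ
  across classes: the pooled frame asks "how variable would the outcome be
  for a pooled-typical person under this class's regression", not "how
  variable is the outcome in the merged population" (which mixes regression
  differences with predictor differences).  It reproduces the published
  pooled-frame solutions of the bundled multigroup estimates, which the
  marginal-variance convention does not.  For shared coefficients and a
  common intercept the two coincide; for G = 1 both reduce to ϕ₀₀,g.

## Standardization frames

All frames apply the same formulas with different reference moments
(κ, Φ, ϕ₀₀):

    γ_j•  = (γ_j + Σ_{k≠j} ω_jk κ_k + 2 ω_jj κ_j) √ϕ_jj / √ϕ₀₀
    ω_jk• = ω_jk √(ϕ_jjϕ_kk) / √ϕ₀₀,    ω_jj• = ω_jj ϕ_jj / √ϕ₀₀
    ψ•    = ψ / ϕ₀₀,    R² = 1 − ψ•

These are algebraic identities obtained by substituting
ξ_j = √ϕ_jj ξ_j* + κ_j into the structural equation — no distributional
assumption enters the coefficient formulas themselves (only ϕ₀₀ needs
one).  Consequences verified as properties: the solution is invariant to
affine rescaling of the predictors (the purpose of standardizing); with no
product terms it reduces to the classic γ√ϕ_jj/√ϕ₀₀ and is
mean-invariant; an OLS fit of the standardized outcome on standardized
predictors and their raw products over simulated draws recovers every
coefficient; and z-scoring the product variables themselves provably does
not (each product coefficient gets divided by the product's standard
deviation, e.g. √(2+4κ*²) for quadratics), which the suite asserts as a
negative control.

Conventions where a choice had to be made:

- In the pooled frame the *pooled* means enter the linear correction
  terms, so a pooled linear effect is the effect for a person at the
  pooled average — this is what makes groups comparable on one metric and
  it reproduces the published pooled solutions.
- ψ°_g divides each class's ψ_g by the common pooled ϕ₀₀ (consistent with
  both published ψ° values).
- Standardized intercepts are reported as 0: each class's equation is
  centered at its own conditional outcome mean.
- Standardized covariances (`phi_std` off-diagonals) use the correlation
  convention ϕ_jk,g/√(Φ_jjΦ_kk) in every frame, matching the within-frame
  convention of published tables.  (Published pooled-frame covariance
  entries that instead divide by the product of pooled *variances* are an
  internal inconsistency we do not reproduce.)
- In `indirect` mode a single ψ is enforced; class-specific ψ_g are
  allowed only in `direct`/`multigroup` modes.
- Simple-slope levels default to −1/0/+1 reference-frame SDs (the usual
  low/average/high convention), over a default focal grid of [−3, 3].

## Monte-Carlo oracle and synthetic data

`mc_oracle` is both the synthetic-data generator and the brute-force
verifier: class labels ~ categorical(π), ξ | class Gaussian, η assembled
from the class's structural equation.  The generator emulates exactly the
latent generative model above — it does *not* simulate a measurement model
(indicators, loadings, measurement error) or estimation noise, so passing
oracle checks demonstrates the correctness of the standardization algebra
given the parameters, not robustness of any estimator on real indicator
data.  Verification z-scores the outcome and predictors with the
closed-form reference moments and fits OLS (statsmodels); because the
identities are exact, the regression is correctly specified and |z| < 3
per coefficient at n = 10⁶ is the expected behavior, not a tuned
tolerance.  Comparisons are always scaled by OLS standard errors, never by
fixed absolute cutoffs.  Default draws: 10⁶ for headline oracle runs
(≈ seconds), 2–4 × 10⁵ in routine tests to keep the suite fast.

## Numerical choices

- Weight sums within 1e−6 of 1 are renormalized; larger deviations are
  rejected.  Φ_g must be symmetric positive definite (eigenvalue tolerance
  −1e−10 after symmetrization) — lenient because published inputs are
  rounded to 3 decimals.
- All assembled covariance matrices are symmetrized as (M + Mᵀ)/2; the
  extended covariance is checked for PSD within a scaled 1e−8 tolerance to
  flag invalid inputs.
- Comparisons against published 3-decimal tables use ±0.002 absolute: the
  inputs themselves carry 3 decimals, so higher agreement is not
  meaningful.
- Product terms are ordered interactions-first, then quadratics, matching
  the γ₃, γ₄, γ₅ numbering of applied tables for p = 2.

## Limitations

- No standard errors, t- or p-values for standardized estimates (a delta
  method over the full parameter vector would be required).
- Single latent outcome; within-class predictor distributions must be
  Gaussian (the nonnormality handled is exactly the mixture-induced kind).
- No estimation: parameters come from an external fit, and the
  standardization inherits whatever bias or imprecision that fit has.
- Moments are used through order four only; spline/multilevel nonlinear
  structures need different machinery.
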