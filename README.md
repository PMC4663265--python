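# semstd

Correct standardization of linear, interaction, and quadratic effects in
structural equation models with latent classes or observed groups.

## The problem

A nonlinear structural model for a latent outcome η and latent predictors
ξ₁, …, ξ_p,

    η_g = α_g + Σ_j γ_j,g ξ_j,g + Σ_{j≤k} ω_jk,g ξ_j,g ξ_k,g + ζ_g,
    ζ_g ~ N(0, ψ_g),   (ξ_g) ~ N(κ_g, Φ_g),   g = 1, …, G,

cannot be standardized the way linear SEM software does it.  Product terms
of standardized predictors have neither zero mean nor unit variance, so
z-scoring them gives wrong effect sizes; and when the predictor means κ_g
are free (latent classes, multiple groups, uncentered predictors), the
*linear* effects pick up mean-dependent corrections from the nonlinear
terms.  Distribution-analytic estimators (LMS/QML and mixture extensions)
additionally never estimate the product-term (co)variances, so the implied
outcome variance ϕ₀₀ — the denominator of every standardized coefficient —
has to be derived from the model itself.

`semstd` computes, for any p ≥ 1 and G ≥ 1:

- the implied outcome variance ϕ₀₀,g within a Gaussian class, from the
  uncentered product-moment (Isserlis) identities;
- the marginal moments and implied outcome variance under the **nonnormal
  mixture marginal** (indirect applications, e.g. NSEMM), where third and
  fourth moments of the mixture must be used instead of Gaussian formulas;
- correctly standardized coefficients in three reference frames — each
  class's own moments (**within**), the pooled moments across classes or
  groups (**pooled**), or a designated **reference** class:

      γ_j•  = (γ_j + Σ_{k≠j} ω_jk κ_k + 2 ω_jj κ_j) √ϕ_jj / √ϕ₀₀
      ω_jk• = ω_jk √(ϕ_jj ϕ_kk) / √ϕ₀₀        (j < k)
      ω_jj• = ω_jj ϕ_jj / √ϕ₀₀
      ψ•    = ψ / ϕ₀₀,   R² = 1 − ψ•

- standardized class/group means, standardized mean differences, simple
  slopes at chosen moderator levels, and a seeded Monte-Carlo oracle that
  verifies every closed form by brute force.

It is aimed at researchers who fit latent interaction/quadratic models or
structural equation mixture models (e.g. with Mplus' XWITH) and need
defensible effect sizes afterwards: the procedure needs only the
unstandardized estimates, the class proportions, and the latent predictor
means and covariances.

## Worked example

The bundled parameter sets describe reading skills regressed on reading
attitude and online reading activities (interaction + two quadratics) for a
two-class mixture and a two-group (gender) model.

```python
from semstd import datasets, standardize_pooled, standardized_mean_difference

model = datasets.reading_indirect()     # nonnormal predictors, shared coefficients
sol = standardize_pooled(model)
print(round(sol.gamma_lin_std[0], 3))   # 0.514  linear effect of attitude
print(round(sol.gamma_quad_std[1, 1], 3))  # -0.085  quadratic (saturation) effect
print(round(sol.psi_std, 3))            # 0.649  -> R^2 = 35% explained variance

gender = datasets.reading_by_gender()
female, male = standardize_pooled(gender)
print(round(female.gamma_lin_std[0], 3))   # 0.474  attitude effect, pooled frame
print(round(standardized_mean_difference(gender, 0, 0, 1), 3))  # 0.532
```

The 0.514 is the standardized effect of reading attitude for a student at
the average attitude level of the whole (nonnormal) population; 0.532 is
the female–male attitude gap in pooled standard-deviation units.  The
`examples/` directory contains one short script per capability (within
frames, mixture frames, multigroup pooling, simple slopes, and the
Monte-Carlo oracle), each printing the numbers it computes.

A thin CLI wraps the same functions:

```sh
semstd standardize examples/data/reading_by_gender.json --frame pooled --out table.csv
semstd oracle examples/data/reading_indirect.json --n 1000000 --seed 42
```

## Scope

Estimation itself (EM/Mplus fitting of the mixture SEM), measurement-model
specification and invariance testing, fit indices, and standard errors of
standardized estimates are out of scope: `semstd` starts from estimated
unstandardized parameters.  See `docs/methods.md` for the derivations,
conventions, and limitations.
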