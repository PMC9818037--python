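# copulasurv

Archimedean-copula survival models for **paired right-censored failure
times** — two event times per subject that cannot be treated as
independent, such as the times to right and left kidney failure in a
hospital cohort.  Paired organs share genetics and exposures, so
analyzing each organ's time with an ordinary (independent-subjects)
survival model biases the estimates; `copulasurv` models the two times
jointly while keeping the marginal regressions interpretable.

It is aimed at biostatisticians and epidemiologists analyzing
bivariate time-to-event registries, and at methodologists who need a
tested reference implementation of the two-stage copula-survival
estimator with a matching synthetic-cohort generator.

## The model

For subject i with covariates z, the joint survivor function couples two
parametric marginal survival functions through a one-parameter
Archimedean copula C_η (Clayton, Gumbel or Joe):

    S(t₁, t₂ | z) = C_η( S₁(t₁ | z), S₂(t₂ | z) )

Margins are Weibull or Gompertz proportional-hazards, or log-logistic
proportional-odds, with one coefficient vector β shared by the two
organs (exp(β) is an odds ratio under the PO margin).  Each subject
enters the likelihood through its censoring pattern (δ₁, δ₂) ∈
{(1,1), (1,0), (0,1), (0,0)} via the copula density, its partial
derivatives, or the copula itself.  Dependence is summarized by
Kendall's τ, a closed-form (Clayton: τ = η/(η+2); Gumbel: τ = (η−1)/η)
or series (Joe) function of η.  Estimation is two-stage maximum
likelihood (margins first, then η, then a joint refinement); models are
compared across the 3 × 3 margin × copula grid by AIC/BIC.  See
`docs/methods.md` for the full specification.

## Worked example

Simulate a study-like cohort of 431 patients (Clayton dependence at
τ = 0.41 over log-logistic margins, study-realistic covariate
frequencies and effect sizes, shared administrative/dropout censoring)
and fit the joint model:

```python
from copulasurv import CopulaSurvivalModel, default_config, generate_cohort

cfg = default_config(n=431, seed=7)
df, manifest = generate_cohort(cfg)
model = CopulaSurvivalModel.from_dataframe(
    df, covariates=["male", "age_36_55", "age_56_plus", "family_history",
                    "hypertension", "diabetes", "anemia", "obesity"])
res = model.fit()
print(res.summary())
```

```
Bivariate copula survival model
================================================================
Margins:  loglogistic (PO, shared coefficients)
Copula:   clayton    n = 431
loglik = -2028.16   AIC = 4074.32   BIC = 4110.92   K = 9
eta = 1.66   Kendall tau = 0.45
----------------------------------------------------------------
                estimate    se      z  p_value    or  ci_low  ci_high
variable
male              -0.066 0.192 -0.342    0.733 0.936   0.642    1.365
age_36_55          0.151 0.235  0.643    0.520 1.163   0.734    1.841
age_56_plus        0.864 0.226  3.818    0.000 2.373   1.523    3.699
family_history     0.606 0.191  3.172    0.002 1.832   1.260    2.664
hypertension       1.020 0.201  5.084    0.000 2.773   1.872    4.109
diabetes           0.625 0.196  3.189    0.001 1.868   1.272    2.742
anemia            -0.095 0.197 -0.482    0.630 0.910   0.618    1.338
obesity            0.372 0.192  1.940    0.052 1.451   0.996    2.112
eta                1.662 0.331  5.018    0.000   NaN     NaN      NaN
----------------------------------------------------------------
baselines: shape1=3.736 scale1=2521 shape2=3.228 scale2=2710
```

Reading the output: `eta = 1.66` is the fitted Clayton dependence
parameter, i.e. Kendall's τ ≈ 0.45 between the two failure times after
adjusting for covariates (at this single-cohort size the estimate sits,
as expected, within sampling error of the generating τ = 0.41).  Each
covariate row gives the shared log-odds coefficient, its Wald test and
the failure odds ratio with 95% CI — here hypertension (OR 2.77) and
age ≥ 56 (OR 2.37) carry clear effects at n = 431, while weaker
generating effects (male, anemia) are not resolved at this sample size.
`K = 9` counts the eight coefficients plus η in AIC/BIC.

Other entry points: `compare_grid` (the nine-model AIC/BIC table),
`screen_univariable` (the 25% candidate screen), `linearization_coords`
and `copula_scatter` (adequacy diagnostics), and a CLI with the verbs
`simulate`, `describe`, `screen`, `compare`, `fit`, `diagnose` and
`run` (full pipeline from a JSON config):

```sh
copulasurv simulate --n 431 --seed 7 --out cohort.csv
copulasurv fit cohort.csv --margin loglogistic --copula clayton
```

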