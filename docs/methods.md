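# Methods note

This note records the statistical model implemented by `epitransport`, the
assumptions it relies on, the modelling choices that were open and how they
were settled, and the known limitations. It documents what the code does, not
claims beyond what the code computes.

## Estimand

With `S = 1` for study rows, `S = 0` for target rows, covariates
`Z = (age, parity, education)`, binary exposure `A` and binary outcome `Y`,
the parameter is the target-population average treatment effect on the
risk-difference scale,

```
ψ = E(Y¹ − Y⁰ | S = 0).
```

Exposure and outcome are observed only for study rows; the target contributes
covariates.

## Identification assumptions

Checkable from data (surfaced by `epitransport.diagnostics`):

1. **Treatment positivity** — `0 < P(A = 1 | S = 1, Z) < 1` for every covariate
   pattern with positive study mass.
2. **Selection positivity** — every covariate pattern with positive target
   mass has positive probability of appearing in the study,
   `P(S = 1 | Z) > 0`.

Untestable (reported as a documentation checklist, never pass/fail):

3. Conditional treatment exchangeability within the study (no unmeasured
   confounding).
4. Conditional exchangeability for selection: the covariates `Z` capture every
   difference between populations that affects the outcome mechanism —
   graphically, no selection node points into `Y` after conditioning on `Z`.
5. No interference; consistency of the treatment definition across
   populations.

The `diagrams` module implements the graphical side of assumption 4: given a
DAG, the set of selection-marked nodes, and the covariates measured in the
target, it removes incoming arrows to the exposure and tests d-separation of
the selection nodes from the outcome, returning `direct` (separated by the
empty set), `via_recalibration` (separated by a minimal measured subset,
reported), or `not_identified_by_rule`. `trivial` is returned only on the
caller's explicit assertion that exposure and outcome are observed in the
target itself, since that fact lives outside the diagram. d-separation uses
`networkx.is_d_separator`; an independent brute-force path-enumeration oracle
lives in the test suite.

## Estimator

Transport-TMLE, in five steps:

1. **Initial outcome model** — logistic regression of `Y` on
   `a + age + parity + education + a:education` fit on study rows (default
   formula; configurable). The exposure-by-education interaction matches the
   generating mechanism and makes education's effect modification estimable.
2. **Treatment model** — logistic `a ~ age + parity` on study rows.
3. **Selection model** — logistic `s ~ age + I(age**2) + parity + education`
   on the stacked sample. The quadratic age term is part of the default
   because the two populations' age laws are truncated normals with different
   scales, whose log density ratio is quadratic in age; a linear-in-age
   selection model can never be correctly specified under the generator.
4. **Fluctuation** — clever covariates
   `H₀ = (1−A)(1−pS)/[pS(1−pA)]`, `H₁ = A(1−pS)/(pS·pA)`, with `pS` and `pA`
   truncated to `(0.001, 0.999)` before weights are formed (truncation counts
   are reported). A no-intercept logistic regression of `Y` on `(H₀, H₁)` with
   offset `logit E⁰` yields `(ε₀, ε₁)`; the updated predictions solve the
   efficient-score equations `Σ Hₐ (Y − E*) = 0` exactly. A linear
   (ordinary-least-squares) fluctuation is available as an option; it solves
   the same score equations but can leave `[0, 1]` and is truncated on
   prediction.
5. **Standardization** — `ψ̂ = mean over target rows of E*(1, z) − E*(0, z)`.

When the initial outcome model is correctly specified and fit by maximum
likelihood, the score equations are already nearly solved at `ε = 0`, so the
fitted fluctuation parameters are near zero; the acceptance suite checks
`|ε| < 0.05` at n = 100,000.

## Inference

The per-unit efficient influence curve, with `p₀ = P(S = 0)` estimated by the
target fraction of the stacked sample of size `N`:

```
D_i = S_i (H₁ᵢ − H₀ᵢ)(Yᵢ − E*ᵢ)/p₀  +  (1 − S_i)(E*(1,Zᵢ) − E*(0,Zᵢ) − ψ)/p₀
```

`mean(D) = 0` holds exactly at the TMLE solution (a tested invariant), and
`se = sqrt(Var(D)/N)`, `CI = ψ̂ ± 1.96·se`.

Two variance estimates are provided:

* `variance="residual"` — the classical sample variance of the realized `D_i`.
  This is anti-conservative in small samples for two identifiable reasons:
  the fluctuation shifts `E*` toward the observed `Y` exactly at high-weight
  points, mechanically shrinking the squared residuals where they contribute
  most; and the sample mean of the heavy-tailed `(H₁−H₀)²` over the study
  rows is itself a noisy estimate of its expectation.
* `variance="plugin"` (default) — the expected-information analogue: `Var(D)`
  is estimated by the mean over the *stacked* sample of the model-based
  conditional second moment `E(D² | Z)`, integrating the population-membership,
  exposure, and outcome Bernoulli draws out analytically under the fitted
  models:

  ```
  E(D²|Z) = pS·[pA·H₁²·e₁(1−e₁) + (1−pA)·H₀²·e₀(1−e₀)]/p₀²
          + (1−pS)·(q₁ − q₀ − ψ)²/p₀²
  ```

  with `e_a` the initial counterfactual predictions and `q_a` the updated
  ones. Both forms estimate the same asymptotic variance; the plug-in form
  removes the Monte-Carlo noise of the realized weights from the standard
  error. The acceptance suite verifies 93–97% empirical coverage of the
  oracle ATE over 500 scaled-down replicates with the default; the residual
  form measurably under-covers at those sizes, which is why it is not the
  default despite being the textbook formula.

Coverage is evaluated against the *marginal* (population-level) oracle ATE:
the EIC's target-side term prices in target-covariate sampling, so the CI is
an interval for the population parameter, not for the ATE conditional on the
realized target table.

## Synthetic-data generator

The real cohort/register data are sensitive; the generator reproduces only
what is printed:

* **Margins** — age median/IQR, parity percentages (0/1/2+), education
  percentages (high/medium/low) for each population; printed percentages are
  renormalized to sum to one (they are rounded in the source).
* **Age** — truncated normal on `[15, 50]` with location = median and
  scale = IQR/1.349 (the minimal-assumption fit to a median and IQR);
  optionally a two-piece (split) normal matching both quartiles exactly, for
  skew sensitivity analyses.
* **Independence** — age, parity and education are sampled independently,
  because only marginal distributions are published. This is the single most
  consequential simplification: it weakens age–parity confounding relative to
  the real joint data, which lowers the *crude* study risk difference (the
  generator's population-level crude RD is 21.98% against a published 24.4%)
  while leaving the adjusted and transported contrasts, which remove that
  confounding, in close agreement with the published values.
* **Exposure** — `P(A=1|Z) = plogis(0.1·(age − ref) − 0.3·I(parity=1) −
  0.5·I(parity=2))` with `ref` the population's realized mean age by default.
* **Outcome** — `P(Y=1|A,Z) = plogis(0.6A + 0.2·(age − ref_y) − 0.1·I(par=1)
  − 0.3·I(par=2) + 0.4·I(edu=med) + 0.6·I(edu=low) + 0.3A·I(edu=med)
  + 0.5A·I(edu=low))`.
* **Outcome age reference** — fixed at 33 years for *both* populations
  (configurable). Centering the outcome model at each population's own mean
  age would make the outcome mechanism itself differ between populations — an
  implicit selection arrow into `Y` — under which the transported estimand is
  not identified and no estimator can match the oracle. Centering choices for
  the *exposure* model are population-specific without harm, since the
  transport machinery models the exposure mechanism separately anyway.
* **Oracle** — `true_target_ate` evaluates
  `mean over target rows of ρ(1, z) − ρ(0, z)` in closed form from the
  generator coefficients, with an optional Monte-Carlo cross-check.
* **Reproducibility** — covariates, exposure and outcome use independent
  substreams spawned from one seed (`numpy.random.SeedSequence`), so a
  population's covariates are identical whether or not outcomes are drawn.

## Numerical choices

* Nuisance models are fit with `statsmodels` GLM (binomial family, formula
  interface); categorical dtypes make parity and education enter as factor
  levels.
* Predicted probabilities are clipped to `[1e-9, 1 − 1e-9]` before logits;
  selection/treatment probabilities are truncated to the configured bounds
  (default `(0.001, 0.999)`) with counts reported.
* Bootstrap CIs for the crude and g-computation estimates are percentile
  intervals over resampled rows; `n_boot=0` skips them.
* The Wald z-quantile is fixed at 1.96.

## Limitations

* Covariate independence in the generator (above): crude-contrast reproduction
  is borderline by construction; do not treat the generator as a model of the
  real joint covariate law.
* The EIC variance assumes correctly specified nuisance models for full
  efficiency; under misspecification the point estimate retains double
  robustness (either the outcome model, or the treatment-and-selection
  models, must be correct) but the plug-in variance inherits the fitted
  models' errors.
* The positivity report flags estimated violations descriptively; truncation
  bounds are an estimation device, not a fix for structural non-overlap.
* The transportability classifier is sound for the d-separation rule it
  implements; it does not search over alternative identification strategies
  (e.g., front-door-style formulas), and its minimal-set search is exhaustive
  and therefore intended for diagrams of at most ~10 covariates.
* All inference is for complete cases; rows with missing required fields are
  dropped and counted, nothing is imputed.
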