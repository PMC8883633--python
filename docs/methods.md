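# Methods

## Setting and model

`hcpmediate` targets two-level cluster-randomised trials: individuals
(students) nested in clusters (schools), treatment `T_j ∈ {0,1}` allocated at
cluster level, and a continuous mediator `m_ij` and outcome `y_ij` measured on
individuals. All models are Gaussian linear mixed models; mediators or
outcomes needing non-identity links are out of scope.

The mediation design is 2-1-1: treatment (level 2) → mediator (level 1) →
outcome (level 1). Because the mediator exists at both levels — individually
and as a cluster aggregate — its effect on the outcome decomposes into a
within-cluster (individual) path `b_w` and a contextual path `b_b`, the effect
of the cluster's mediator level beyond the individual's own. The baseline
outcome model uses the *uncentred* mediator alongside the observed cluster
mean, so the cluster-mean coefficient is directly the contextual effect.
Cluster means are manifest (observed means of retained records), not latent:
this matches the uncentred-plus-cluster-mean formulation, at the price of a
finite-cluster-size attenuation discussed below.

A healthy context paradox is a treatment-by-mediator interaction in which
treatment *strengthens* the adverse mediator→outcome association. It can act
at either level, giving the two tests:

* **Test 1 (contextual):** add `T_j × m̄_j` to the baseline outcome equation
  (coefficient `γ_B`). Wald comparison to baseline constrains 1 parameter.
* **Test 2 (individual):** cluster-mean centre the mediator, give the
  deviation a random slope `s_j ~ N(0, τ₁²)` (covariance `τ₀₁` with the
  random intercept), and regress the slope on treatment — the fixed product
  term `d`. With the deviation in the model, the cluster-mean coefficient
  approximates `b_w + b_b` rather than `b_b` alone, and the deviation's main
  coefficient is the control-arm within-cluster slope. Wald comparisons
  constrain `(d, τ₁², τ₀₁)` against the baseline (df = 3) and `(d, τ₀₁)`
  against the reduced model that keeps the random slope (df = 2). The
  baseline for the df = 3 comparison is defined as having *no* random-slope
  structure.

Classification is directional: with the default scale conventions (mediator
higher-is-worse, outcome higher-is-better) the adverse association is
negative, so `paradox_supported` requires a significant moderation with a
negative sign; a significant positive sign is `opposite_direction` (an
enhanced benefit where the mediator remains high); anything else is
`not_supported`. Flipping exactly one direction flag flips the required sign.
A non-significant treatment→mediator path fails the mediator screen and emits
a prominent warning — mediators that the intervention does not move are not
useful mediators — but never blocks either test, since within- and
between-level effects of opposite sign can mask each other in a pooled test.

## Estimation

Both equations are fitted as separate mixed models by **maximum likelihood**
(not REML), so Wald and likelihood-ratio comparisons remain coherent when
fixed effects differ between nested specifications. Indirect effects combine
the two fits treating `â` as independent of `(b̂_w, b̂_b)` — exact in the
generative model's factorisation and asymptotically justified for correctly
specified Gaussian models; this is an approximation to a joint fit.
Indirect-effect uncertainty is reported two ways: delta-method intervals, and
seeded Monte-Carlo percentile intervals from 10,000 normal draws of the path
estimates (count configurable). The total indirect effect is computed as the
sum of the individual and contextual components, so the decomposition is
additive exactly, by construction.

### The mixed-model engine

The marginal likelihood is profiled over the fixed effects (GLS) and the
residual variance; optimisation runs over the relative Cholesky factor of
`G/σ²` (diagonal bounded at zero), so every iterate maps to a valid
covariance matrix. The profiled deviance depends on the data only through
per-cluster cross-products, making each evaluation O(J) whatever the cluster
sizes. The optimiser is L-BFGS-B followed by a deterministic bounded
Nelder-Mead polish (initial simplex 1e-4 around the quasi-Newton solution,
`xatol` 1e-8); there are no random restarts, so identical inputs give
identical fits. Non-convergence is flagged on the result, never silent.

The parameter covariance is the inverse **observed information** at the
optimum, computed jointly over fixed effects and variance components in
natural units — necessary because Test 2's Wald comparisons constrain
variance components. The fixed-effect block is analytic (`X'V⁻¹X`); the
cross and variance blocks use central finite differences of the exact
log-likelihood (relative step 1e-3, floor 1e-2·σ²), with one-sided fallbacks
when a step would leave the region where the matrix-determinant-lemma
expression is defined. A robust (cluster-sandwich) covariance is not
currently offered; single-coefficient p-values use the two-sided normal
reference, multi-parameter Wald tests the chi-square reference.

Two caveats are surfaced explicitly. (1) Wald tests constraining a variance
component estimated at its boundary (`τ₁² = 0`) use the ordinary chi-square
reference, which is anti-conservative there; results carry a caveat string
rather than a corrected (mixture) reference, mirroring common practice for
these comparisons. (2) With all-singleton clusters the intercept/residual
split is unidentified; fixed effects still reduce to OLS and the fit is
flagged.

## The synthetic-trial generator

The generator mirrors the analysis models with a clean latent within/between
separation:

```
mu_Mj = α₀ + a·T_j + u^M_j                     u^M_j ~ N(0, τ²_M)
m_ij  = mu_Mj + e^M_ij                          e^M_ij ~ N(0, σ²_M)
y_ij  = β₀ + c′·T_j + (b_b + b_w + γ_B·T_j)·mu_Mj
        + (b_w + d·T_j + s_j)·(m_ij − mu_Mj) + u^Y_j + e^Y_ij
```

with `(u^Y_j, s_j)` jointly normal `(τ₀², τ₁², τ₀₁)` and `e^Y ~ N(0, σ²)`.
`γ_B` plants a contextual paradox, `d` an individual one. Allocation is
balanced; cluster sizes are constant by default, optionally uniform on an
integer range. Replicate `r` of an operating-characteristics run uses seed
`base + r`, so any replicate is reproducible in isolation.

Defaults (scenario `s0`) emulate a school trial of 40 schools × 150
students: mediator on a victimisation-like scale (`α₀ = 1.0`, `τ²_M = 0.05`,
`σ²_M = 0.8`), outcome on a wellbeing-like scale (`β₀ = 23`, `τ₀² = 0.5`,
`σ² = 12`, outcome ICC ≈ 0.04), paths `a = −0.30`, `b_w = −0.687`,
`b_b = 0.34`, `c′ = 0.25`, and no moderation (`γ_B = d = 0`, `τ₁² = 0`). The
`b` paths are set to published estimates from a trial of this design; the
variances were chosen so the analytic standard errors of the key paths land
at the same order of magnitude as that trial's printed standard errors
(SE(b_w) ≈ 0.05, SE(b_b) ≈ 0.5, SE(d) ≈ 0.1); `a` is a plausible choice of
the package's own, as no published value was available. The planted-effect
scenarios size their moderation at roughly three analytic standard errors
(`γ_B = −3.0`; `d = −0.35` with `τ₁² = 0.02`, `τ₀₁ = −0.03`), targeting
~80% power.

**Latent vs manifest means.** Generation uses the latent cluster mean
`mu_Mj`; estimation regresses on the observed mean `m̄_j = mu_Mj + ē_j`.
Between-level coefficients are therefore attenuated by the reliability
`τ²_M / (τ²_M + σ²_M/n_j)` (≈ 0.90 at the defaults) — visible as a small
downward shift in recovered `b_b` that stays within Monte-Carlo error at the
default replicate counts, and as the gap between the Test 2 cluster-mean
coefficient and the exact `b_w + b_b`.

Under null moderation and no random slope, the generated outcome's
within-arm intraclass correlation has the closed form

```
ICC_y = ((b_w + b_b)²·τ²_M + τ₀²) / ((b_w + b_b)²·τ²_M + τ₀² + b_w²·σ²_M + σ²)
```

which the test suite checks against a large simulated sample.

**What the generator does not emulate:** attrition and missingness,
covariates, non-normal or bounded scales (real victimisation scores are
skewed and floor-heavy), informative cluster sizes, and measurement error
beyond the within-cluster sampling of the mediator. Passing tests therefore
demonstrate correctness of the estimators and calibration under the stated
Gaussian generative model, not robustness to these real-data features.

## Validation studies and problem sizes

The acceptance script and test suite use: single datasets at the default
40 × 150 for structural checks; 200 replicates at 40 × 150 for parameter
recovery; 1000 replicates at 40 × 50 for type-I error (clusters, which drive
calibration of the between-level test, stay at 40; cluster size is reduced
because within-cluster information is already ample at n = 50); 200
replicates per planted scenario for power; and one 400 × 200 dataset for the
between-coefficient-sum property. Measured type-I error of Test 1 sits near
0.06–0.07 at 40 clusters — the mild inflation expected of a normal-reference
test on ~40 effective observations with ML variance estimates — and Test 2's
near 0.05.

## Known limitations

* Separate-equations fitting (not a joint SEM); delta-method independence of
  `â` from the `b̂` paths.
* No small-sample df corrections (Satterthwaite/Kenward-Roger); with few
  clusters, between-level tests run slightly liberal.
* Boundary Wald tests as described above.
* Listwise deletion of records missing any analysis variable (counts are
  logged); no weighting, no third nesting level, binary treatment only.
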