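# Methods

## Models

### Heckman's sample-selection model

The outcome equation is Y_i = X_i'β + ε_i with ε_i ~ N(0, σ₁²); selection
follows a latent process Ỹ_i = X̃_i'γ + ε̃_i with ε̃_i ~ N(0, σ₂²),
cov(ε, ε̃) = σ₁₂, and Y_i observed iff Ỹ_i > 0. The latent scale σ₂ is not
identified in a probit selection model and is fixed at 1 throughout, so the
probit index is X̃'γ. The selection design X̃ must contain at least one
instrument for selection Z excluded from X; without that exclusion the
Mills-ratio regressor is near-collinear with X and the fit is rejected with
a collinearity diagnostic.

Selection on the latent scale gives E(Y | X, Ỹ > 0) = X'β + σ₁₂·λ where λ
is the inverse Mills ratio. The hazard form λ = φ(a)/Φ(a) at the probit
index a = X̃'γ is used: it equals the textbook φ(Λ)/(1−Φ(Λ)) at Λ = −a by
the symmetry of the normal density, and evaluating it as
exp(log φ − log Φ) keeps it finite over at least |a| ≤ 40.

**Two-step estimator** (the default): probit of R on X̃, then OLS of Y on
[X, λ̂] over selected rows. The coefficient on λ̂ is σ̂₁₂ = ρ̂σ̂₁.
Standard errors use the classical two-step covariance correction: with
δ_i = λ_i(λ_i + a_i), σ̂² = (e'e + σ̂₁₂²Σδ_i)/n₁ and
V = σ̂²(W'W)⁻¹[W'(I − ρ̂²Δ)W + ρ̂²(W'ΔX̃)V̂_γ(X̃'ΔW)](W'W)⁻¹, which
accounts for both the heteroskedastic selected-sample residuals and the
estimated first stage. A plain-OLS-SE mode exists behind a flag for
diagnostics only.

**Maximum likelihood**: the bivariate-normal selection likelihood is
maximized over (β, γ, log σ₁, artanh ρ) by BFGS on the per-observation
average (so gradient tolerances do not scale with n; gtol 1e-8, 500
iterations), started at the two-step solution; SEs come from the inverse
negative Hessian (finite differences) with a delta-method map back to
(σ₁, ρ). Estimates of |ρ| within 1e-6 of 1 attach a boundary warning.

**Binary outcomes** use a censored bivariate probit (latent outcome and
latent selection with correlated normal errors); the bivariate normal CDF
is evaluated through Owen's T function, and coefficients are reported on
the probit scale.

Degenerate inputs: if every individual is selected, or the fitted Mills
ratio is constant given X (e.g. an intercept-only selection design), the
selection model carries no information and the estimator falls back to
complete-case OLS with a warning rather than erroring.

### TTW homogeneous-selection-bias model

Selection bias is δ(X) = E(Y|X,Z,R=1) − E(Y|X,Z,R=0), assumed free of Z.
With working models E(Y|X) = X'β, δ(X) = X'η and logistic propensity
π(X,Z) = expit((X,Z)'α), the joint likelihood is a Bernoulli term for
every individual's R plus a normal term for selected outcomes with mean
X'β + (X'η)(1 − π).

*Partial* optimization (default): α̂ by logistic regression, then the
outcome part maximized with π fixed. Given π the stage-2 problem is a
Gaussian linear model in the augmented design [X, (1−π)X], so the stage-2
maximizer is computed exactly by least squares with σ̂² = RSS/n₁ (the
MLE); SEs are the inverse negative Hessian of the stage-2 objective, which
deliberately ignores stage-1 propensity uncertainty. The augmented design
is checked for conditioning (threshold 1e10 on normalized columns): a
propensity model without a useful instrument makes (1−π)X fall into the
span of X and the fit raises an identification error instead of returning
silent garbage.

*Full* optimization maximizes over (β, η, α, log σ²) jointly by BFGS from
the partial solution (gtol 1e-8, 1000 iterations) with SEs from the full
Hessian; a non-positive-definite Hessian raises a flat-likelihood error.

*Binary/Poisson outcomes*: the bias term enters additively on the link
scale, link E(Y|X,Z,R=1) = X'β + δ(X)(1−π), so stage 2 is an ordinary
GLM in the augmented design with no σ² parameter. The additive-link form
is one of several possible conventions (the original development also
admits an odds-ratio-scale bias for binary outcomes); it is isolated
behind the family abstraction so it can be swapped without touching the
optimizer, and no headline quantity depends on the logistic family.

The bias design defaults to the outcome design (δ(X) = X'η) and is
configurable.

### MAR baselines

Complete-case GLM; IPW with a logistic weight model on fully observed
covariates (default: the outcome design, i.e. X but not Z), weights 1/π̂
for selected rows, and sandwich standard errors treating weights as fixed;
and the full-data oracle, available only in simulation. Fitted selection
probabilities below 1e-6 abort the IPW fit listing the offending rows.

### MR estimators

Wald ratio θ̂ = β̂_Y/β̂_X with the second-order SE
√(s_Y²/β̂_X² + β̂_Y²s_X²/β̂_X⁴). 2SLS regresses X on [1, G], then Y on
[1, X̂]; with no adjustment the analytic second-stage SE (residuals from
the original exposure) is reported, and complete-case 2SLS drops rows with
a missing value in any variable of either stage. Adjusted stages replace
the corresponding regression by a Heckman or TTW fit whose selection
design is always [1, G, Z] (or [1, X̂, Z] in the second stage); fitted
exposures X̂ = [1, G]β̂ are then available for all individuals. Because
the analytic SE is invalid under adjustment, requesting it raises a
contract error; SEs come instead from a nonparametric bootstrap over
individuals (default M = 100, failed resamples counted and excluded, >20%
failures aborts). Per-variant summary statistics run one univariate
regression per variant and side; IVW combines them with first-order
weights 1/s_Yj², or second-order weights 1/(s_Yj² + θ̂₁²s_Xj²) plugged in
once from the first-order estimate (the default). IVW on one-sample
statistics logs a sample-overlap caution.

## Generative designs

Regression: Z, X, ε ~ N(0,1) independently, Y = α + βX + ε with α = 1 and
β = 0.1 (0 in the null scenario), and selection
R ~ Bernoulli(expit(α_R + β_R X + γ_R Z + δ_R Y)) with β_R = δ_R = 0.5 and
γ_R = 0.4; Y is masked where R = 0 and n = 10⁴. Variants replace Z or X by
Bernoulli(0.5) (uncentered), generate Y from a logistic or log-linear
Poisson model with the same α, β on the link scale, set β_R or δ_R to 0,
or add direct Z→X / Z→Y effects of 1/3. The instrument-strength grid
varies γ_R over {0, 0.08, 0.2, 0.27, 0.4, 0.6, 0.95} (spanning roughly 0
to 10% of the variation in selection).

MR: G, Z, U, ε_X, ε_Y ~ N(0,1), X = β_X G + U + ε_X,
Y = θX + U + ε_Y with θ ∈ {0, 0.2}. The single-instrument score uses
β_X = √(2/19) ≈ 0.3244 so that G explains exactly 5% of var(X) given unit
confounder and noise variances. With K = 10 variants, allele frequencies
are U(0.1, 0.9), genotypes Binomial(2, f_j), and effects are drawn from
N(0, 0.05²) left-truncated at 0.15 (per-variant effects ≈ 0.15–0.2,
jointly ≈ 5% of var(X)). Selection is logistic with γ_R = 0.5 and
(β_R, δ_R) ∈ {(0,1), (1,0), (0.5,0.5)}; exactly the drivers of selection
are masked. Two-sample designs draw two independent datasets of n = 10⁴
and apply selection only in the sample whose measured variable drives it.

Note the deliberate working-model mismatch: data are selected through a
*logistic* model while Heckman assumes a *probit* selection equation.
This is part of the study conditions — it shows the adjustment is robust
to mild propensity misspecification — and is not to be "fixed".

The selection intercept α_R is tuned by Brent root-finding on the
Monte-Carlo marginal selection probability of a 10⁶-individual pilot
sample (deterministic given the seed) so that ~50% of individuals are
selected; with all selection slopes zero the closed form logit(target) is
returned. At the baseline regression setting this reproduces
α_R ≈ −αδ_R = −0.5.

## What the generator does and does not emulate

The generator reproduces the study conditions exactly: effect sizes,
selection strengths, missingness fraction, sample sizes and the
logistic-selection/probit-fit mismatch. It does not emulate linkage
disequilibrium between variants, pleiotropy of the inference instruments,
non-normal outcome errors, covariate measurement error, or realistic
genotyping artefacts. Passing tests therefore demonstrate correctness of
the estimators under the stated models and robustness to the one built-in
misspecification, not performance on arbitrary real cohorts.

## Replication engine and problem sizes

Each replication draws its dataset from an independent child stream of the
master seed (`numpy` `SeedSequence.spawn`), so every run is reproducible
bit-for-bit and methods see identical data within a replication. Metrics
per estimator: mean, empirical SD (ddof 1), mean model SE, 95% coverage of
est ± 1.96·SE around the truth, and power |est/SE| > 1.96 (the type-I
error rate when the truth is 0). Failed fits are logged, counted and
excluded.

The acceptance script uses 2000 replications of n = 10⁴ for the regression
and single-instrument MR scenarios and 500 for multi-instrument 2SLS; the
test suite uses 100–400 replications per scenario. These sizes keep the
Monte-Carlo error of a reported mean below ~0.005 (2000 reps) and ~0.01
(300 reps) for the quantities checked, with test tolerances set at
max(3·SD/√reps, 0.005) from the corresponding benchmark spread.
Bootstrap-based coverage of adjusted 2SLS is exercised at reduced resample
counts (M ≈ 20–25) in the tests; full-scale M = 100 matches the reference
setting and is the library default.

## Design choices made where the design was open

- Whether the reference Heckman runs used two-step or ML is not
  documented; both are implemented and the simulation arms default to the
  two-step estimator (the common package default). The ML path is
  validated separately against grid and oracle checks.
- IPW weight models in MR scenarios are unspecified; the weight model here
  is logistic in G plus whichever of X/Y is fully observed, logged per
  run. IPW is a comparison arm only.
- The single-instrument genetic effect is implemented as β_X = √(2/19),
  the unique value consistent with "G explains 5% of var(X)" under unit
  variances.
- The multi-instrument effect distribution is read as N(0, 0.05²)
  truncated below at 0.15; allele frequencies and effects are redrawn each
  replication.
- Second-order IVW weights use a single plug-in pass of the first-order
  estimate.
- Selection-effect sizes quoted as R² percentages are treated as
  descriptive; the coefficients themselves are primitive.

## Known limitations

- The TTW logistic family uses the additive-logit bias convention (see
  above); odds-ratio-scale homogeneity is not implemented.
- Heckman has no Poisson variant (the selection model has no natural
  count-data analogue in this parameterization); requesting it raises.
- Sandwich SEs for IPW ignore weight-estimation uncertainty, matching
  standard survey practice.
- The 2SLS analytic SE is the classical homoskedastic form; with
  adjustment the bootstrap is mandatory and computationally dominant.
- No pleiotropy-robust MR estimators, multivariable MR, overlap-bias
  corrections, nonparametric propensity/bias models, or
  partial-identification bounds.
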