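# selectmr

Selection-bias adjustment for regression and Mendelian randomization (MR)
analyses with data that are **missing not at random (MNAR)**, using
**instruments for selection**.

## The problem

Epidemiologic and MR studies routinely lose participants in ways that
depend on the very variables under study: disease-progression traits are
only observed in people who developed the disease, questionnaires are
returned more often by healthier participants, and so on. When the
probability of observing an outcome Y depends on Y itself, the data are
MNAR and the usual missing-data fixes — complete-case analysis (CCA) and
inverse probability weighting (IPW) — are biased, because they can only
model selection from fully observed variables.

An *instrument for selection* Z breaks this impasse: a variable observed
for everyone that (i) is associated with selection R given the covariates,
and (ii) is independent of the partially observed variable given the
covariates. Given such a Z, two likelihood-based estimators identify the
full-data regression from selected rows alone:

- **Heckman's sample-selection model.** Outcome Y = X'β + ε₁ with a latent
  probit selection process R = 1{X̃'γ + ε₂ > 0}, X̃ ⊇ Z, and correlated
  normal errors. Selection induces
  E(Y | X, R=1) = X'β + (σ₁₂/σ₂)·λ, where λ = φ(Λ)/(1−Φ(Λ)) is the
  inverse Mills ratio at the probit index. Fitted by the classical
  two-step procedure (probit, then least squares on [X, λ̂] with the
  corrected covariance) or by full-information ML; a bivariate-probit
  variant handles binary outcomes.
- **The TTW homogeneous-selection-bias model** (Tchetgen Tchetgen &
  Wirth). With selection bias δ(X) = E(Y|X,Z,R=1) − E(Y|X,Z,R=0) assumed
  free of Z, the observed-data regression is
  E(Y | X, Z, R=1) = X'β + δ(X)(1 − π(X,Z)) with a logistic propensity
  π(X,Z). The joint likelihood over (β, η, α, σ²) is maximized in full or
  by a partial two-stage procedure; binary and Poisson outcomes enter via
  the link scale.

For MR, each constituent regression of the Wald ratio
θ̂ = β̂_Y/β̂_X, of two-stage least squares (2SLS), or of per-variant
summary statistics combined by inverse-variance weighting (IVW), can be
swapped for a selection-adjusted fit on whichever side is masked
(bootstrap SEs replace the invalid analytic 2SLS formula when a stage is
adjusted). A Monte-Carlo engine regenerates all the study conditions and
reports per-estimator mean, empirical SD, mean model SE, 95% coverage and
power.

## Worked example

```python
import numpy as np
from selectmr import simulate as sim
from selectmr import HeckmanSelectionModel, cca_fit

rep = sim.gen_regression(sim.regression_scenario("baseline"), seed=1)
data = rep["data"]            # n=10,000; true slope 0.1; ~50% of Y masked

print(f"CCA slope:     {cca_fit(data).params[1]:.3f}")
fit = HeckmanSelectionModel(data).fit(method="two-step")
print(f"Heckman slope: {fit.params[1]:.3f} (SE {fit.bse[1]:.3f})")
```

```
CCA slope:     0.036
Heckman slope: 0.086 (SE 0.022)
```

The complete-case slope is attenuated to roughly a third of the true
value 0.1 because individuals with large outcomes are preferentially
selected; the Heckman fit, which uses the instrument for selection Z in
its probit selection equation, recovers the truth within one standard
error.

The same pattern at Monte-Carlo scale, and the MR analogue:

```python
res = sim.run_replications(sim.regression_scenario("baseline"),
                           ["cca", "heckman", "oracle"], n_reps=200, seed=1)
print(res.metrics.round(3).to_string(index=False))
```

```
 method  mean  emp_sd  mean_se  coverage  power  n_failed
    cca 0.046   0.014    0.014     0.045   0.88         0
heckman 0.100   0.024    0.024     0.955   0.99         0
 oracle 0.100   0.010    0.010     0.960   1.00         0
```

From the shell the same runs are available as `selectmr simulate
--scenario baseline --reps 200 --seed 1`, with `selectmr fit` and
`selectmr mr` for single analyses on delimited data files.

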