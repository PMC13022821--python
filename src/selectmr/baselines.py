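"""MAR benchmark estimators: complete-case analysis, inverse-probability
weighting, and the full-data oracle.

These assume data are missing at random and serve as the comparison arms
for the selection-adjusted estimators: complete-case analysis simply drops
rows with a missing outcome; IPW reweights complete cases by the inverse
of a logistic selection probability fitted on fully observed covariates
(robust/sandwich standard errors, weights treated as fixed); the oracle
fits the pre-masking data and is available only in simulations.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm

from .data import SelectionDataset
from .exceptions import ExtremeWeightError, FitError
from .ttw import fit_propensity

__all__ = ["RegressionFit", "WeightedFit", "cca_fit", "ipw_fit", "oracle_fit"]

_PI_FLOOR = 1e-6


class RegressionFit:
    """Minimal regression result: coefficients, standard errors, loglik."""

    def __init__(self, params, bse, llf=None, family="linear", nobs=None):
        self.params = np.asarray(params, dtype=float)
        self.bse = np.asarray(bse, dtype=float)
        self.llf = llf
        self.family = family
        self.nobs = nobs

    def conf_int(self, alpha=0.05):
        from scipy import stats
        z = stats.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - z * self.bse,
                                self.params + z * self.bse])

    def to_dict(self):
        return {"beta": self.params.tolist(), "beta_se": self.bse.tolist(),
                "family": self.family, "loglik": self.llf}


class WeightedFit(RegressionFit):
    """IPW regression result; carries the weights and weight-model tag."""

    def __init__(self, params, bse, weights, weight_model, **kw):
        super().__init__(params, bse, **kw)
        self.weights = np.asarray(weights, dtype=float)
        self.weight_model = weight_model


def _glm_family(family):
    return {"linear": sm.families.Gaussian(),
            "logistic": sm.families.Binomial(),
            "poisson": sm.families.Poisson()}[family]


def _fit_glm(y, X, family, weights=None, robust=False):
    if family == "linear":
        if weights is None:
            res = sm.OLS(y, X).fit()
        elif robust:
            res = sm.WLS(y, X, weights=weights).fit(cov_type="HC0")
        else:
            res = sm.WLS(y, X, weights=weights).fit()
    else:
        kw = {"freq_weights": weights} if weights is not None else {}
        model = sm.GLM(y, X, family=_glm_family(family), **kw)
        res = model.fit(cov_type="HC0") if robust else model.fit()
    return res


def cca_fit(data: SelectionDataset, family="linear") -> RegressionFit:
    """Complete-case GLM of the outcome on the outcome design."""
    sel = data.selected
    if sel.sum() < data.n_outcome_params + 1:
        raise FitError("too few complete rows for a complete-case fit")
    res = _fit_glm(data.outcome[sel], data.outcome_design[sel], family)
    return RegressionFit(res.params, res.bse, llf=float(res.llf),
                         family=family, nobs=int(sel.sum()))


def ipw_fit(data: SelectionDataset, weight_design=None, family="linear") -> WeightedFit:
    """Inverse-probability-weighted GLM with sandwich standard errors.

    The selection probability is fitted by logistic regression of R on
    ``weight_design`` (default: the outcome design, i.e. the covariates X
    but not the instrument for selection).  Complete cases are weighted by
    1 / pi-hat; the robust variance treats the weights as fixed.
    """
    if weight_design is None:
        weight_design = data.outcome_design
    weight_design = np.asarray(weight_design, dtype=float)
    if np.any(~np.isfinite(weight_design)):
        raise ValueError("weight_design must be fully observed for all rows")
    prop = fit_propensity(weight_design, data.selected)
    pi = prop.fitted_pi
    sel = data.selected
    low = np.flatnonzero(pi < _PI_FLOOR)
    if low.size:
        raise ExtremeWeightError(
            f"{low.size} rows have fitted selection probability below "
            f"{_PI_FLOOR:g}", rows=low)
    weights = np.zeros(data.nobs)
    weights[sel] = 1.0 / pi[sel]
    res = _fit_glm(data.outcome[sel], data.outcome_design[sel], family,
                   weights=weights[sel], robust=True)
    return WeightedFit(res.params, res.bse, weights=weights,
                       weight_model=f"logistic({weight_design.shape[1]} cols)",
                       family=family, nobs=int(sel.sum()))


def oracle_fit(outcome_design, outcome, family="linear") -> RegressionFit:
    """GLM on the complete pre-masking data (simulation benchmark)."""
    outcome = np.asarray(outcome, dtype=float)
    if np.any(~np.isfinite(outcome)):
        raise ValueError("oracle fit requires the fully observed outcome")
    res = _fit_glm(outcome, np.asarray(outcome_design, dtype=float), family)
    return RegressionFit(res.params, res.bse, llf=float(res.llf),
                         family=family, nobs=outcome.size)
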