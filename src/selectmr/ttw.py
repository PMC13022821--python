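"""Homogeneous-selection-bias likelihood (Tchetgen Tchetgen & Wirth).

The selection bias of a partially observed outcome is the mean difference
between selected and non-selected individuals at fixed covariates,

    delta(X) = E(Y | X, Z, R=1) - E(Y | X, Z, R=0).

Under the homogeneous selection bias assumption delta depends on the
covariates X but not on the instrument for selection Z, which gives the
observed-data regression

    E(Y | X, Z, R=1) = E(Y | X) + delta(X) * (1 - pi(X, Z)),

with pi(X, Z) = P(R=1 | X, Z) the selection propensity.  With the working
models E(Y|X) = X'beta, delta(X) = X'eta and a logistic propensity
pi = expit((X, Z)'alpha), the likelihood over all n individuals is

    prod_i  Normal(Y_i; X_i'beta + X_i'eta (1 - pi_i), sigma^2)^{R_i}
            * Bernoulli(R_i; pi_i),

maximized either in one go over (beta, eta, alpha, sigma^2) ("full" mode)
or by first fitting the propensity and then maximizing the outcome part
with pi fixed ("partial" mode, the default; its standard errors come from
the inverse negative Hessian of the stage-2 objective and deliberately
ignore propensity uncertainty).  Binary and count outcomes replace the
normal density by a Bernoulli/Poisson likelihood with the bias term
entering additively on the link scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, special
import statsmodels.api as sm
from statsmodels.tools.numdiff import approx_hess1
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .data import SelectionDataset
from .exceptions import (ConvergenceError, FitError, IdentificationError,
                         SeparationError)

__all__ = ["fit_propensity", "PropensityFit", "TTWModel", "TTWResults",
           "ttw_loglik", "ttw_fit_partial", "ttw_fit_full", "ttw_fit_glm"]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)
_COND_MAX = 1e10


class PropensityFit:
    """Logistic selection-propensity fit: coefficients, fitted pi, loglik."""

    def __init__(self, alpha, cov, fitted_pi, llf):
        self.alpha = np.asarray(alpha, dtype=float)
        self.cov = np.asarray(cov, dtype=float)
        self.fitted_pi = np.asarray(fitted_pi, dtype=float)
        self.llf = float(llf)


def fit_propensity(design, selected, maxiter=100) -> PropensityFit:
    """Logistic regression MLE of the selection indicator on (X, Z)."""
    design = np.asarray(design, dtype=float)
    selected = np.asarray(selected).ravel().astype(int)
    if selected.min() == selected.max():
        raise SeparationError("selection indicator is constant; both classes required")
    model = sm.Logit(selected, design)
    try:
        res = model.fit(disp=0, maxiter=maxiter)
    except PerfectSeparationError as err:
        raise SeparationError(f"perfect separation in propensity fit: {err}") from err
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError("propensity logit did not converge",
                               trace=res.mle_retvals)
    if np.max(np.abs(res.params)) > 1e3:
        raise SeparationError("quasi-complete separation (diverging logit coefficients)")
    return PropensityFit(res.params, res.cov_params(), res.predict(), res.llf)


def ttw_loglik(params, data: SelectionDataset, bias_design=None):
    """Log-likelihood at a packed parameter vector.

    ``params`` concatenates (beta [p], eta [p_delta], alpha [q], sigma2);
    the last entry is the raw residual variance and must be positive.
    Returns the sum of the Bernoulli selection term over all individuals
    and the normal outcome term over selected individuals.
    """
    d = data
    B = d.outcome_design if bias_design is None else np.asarray(bias_design, float)
    p = d.n_outcome_params
    pb = B.shape[1]
    q = d.n_selection_params
    if len(params) != p + pb + q + 1:
        raise ValueError("parameter vector has the wrong length")
    beta = params[:p]
    eta = params[p:p + pb]
    alpha = params[p + pb:p + pb + q]
    sigma2 = params[-1]
    if not sigma2 > 0:
        raise ValueError("sigma2 must be positive")
    lin = d.selection_design @ alpha
    sel = d.selected
    # Bernoulli term, every individual: R*log(pi) + (1-R)*log(1-pi)
    ll_bern = np.where(sel, special.log_expit(lin), special.log_expit(-lin)).sum()
    pi = special.expit(lin)
    mean = d.outcome_design @ beta + (B @ eta) * (1.0 - pi)
    resid = d.outcome[sel] - mean[sel]
    ll_norm = (-0.5 * np.log(sigma2) - 0.5 * resid ** 2 / sigma2
               - _LOG_SQRT_2PI).sum()
    if not np.isfinite(ll_bern):
        raise FitError("non-finite Bernoulli term in TTW likelihood")
    if not np.isfinite(ll_norm):
        raise FitError("non-finite normal outcome term in TTW likelihood")
    return ll_bern + ll_norm


class TTWResults:
    """Estimates from a TTW fit.

    Attributes
    ----------
    params, bse : full-data regression coefficients beta and SEs.
    eta, eta_se : selection-bias function coefficients delta(X) = X'eta.
    alpha_prop, alpha_se : logistic propensity coefficients.
    sigma2 : residual variance (linear family only, else None).
    llf : log-likelihood of the joint outcome-and-selection model.
    mode : "partial" or "full"; family : "linear", "logistic" or "poisson".
    """

    def __init__(self, model, params, bse, eta, eta_se, alpha_prop, alpha_se,
                 sigma2, llf, mode, family, converged=True, fit_warnings=()):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.bse = np.asarray(bse, dtype=float)
        self.eta = np.asarray(eta, dtype=float)
        self.eta_se = np.asarray(eta_se, dtype=float)
        self.alpha_prop = np.asarray(alpha_prop, dtype=float)
        self.alpha_se = np.asarray(alpha_se, dtype=float)
        self.sigma2 = sigma2
        self.llf = llf
        self.mode = mode
        self.family = family
        self.converged = converged
        self.fit_warnings = list(fit_warnings)

    @property
    def fitted_pi(self):
        return special.expit(self.model.data.selection_design @ self.alpha_prop)

    def conf_int(self, alpha=0.05):
        from scipy import stats
        z = stats.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - z * self.bse,
                                self.params + z * self.bse])

    def to_dict(self):
        return {
            "mode": self.mode,
            "family": self.family,
            "beta": self.params.tolist(),
            "beta_se": self.bse.tolist(),
            "eta": self.eta.tolist(),
            "eta_se": self.eta_se.tolist(),
            "alpha": self.alpha_prop.tolist(),
            "alpha_se": self.alpha_se.tolist(),
            "sigma2": self.sigma2,
            "loglik": self.llf,
            "converged": self.converged,
            "warnings": self.fit_warnings,
        }

    def summary(self):
        d = self.model.data
        out = pd.DataFrame({"coef": self.params, "std err": self.bse},
                           index=d.outcome_names)
        bias = pd.DataFrame({"coef": self.eta, "std err": self.eta_se},
                            index=[f"delta_{n}" for n in d.outcome_names[:len(self.eta)]])
        prop = pd.DataFrame({"coef": self.alpha_prop, "std err": self.alpha_se},
                            index=d.selection_names)
        lines = [
            "TTW homogeneous-selection-bias model",
            f"mode: {self.mode}   family: {self.family}   n = {d.nobs} "
            f"(selected {d.n_selected})",
            "",
            "Full-data regression E(Y|X):",
            out.to_string(float_format=lambda v: f"{v: .4f}"),
            "",
            "Selection-bias function delta(X):",
            bias.to_string(float_format=lambda v: f"{v: .4f}"),
            "",
            "Propensity pi(X, Z) (logistic):",
            prop.to_string(float_format=lambda v: f"{v: .4f}"),
            "",
            f"log-likelihood: {self.llf:.4f}"
            + (f"   sigma2: {self.sigma2:.4f}" if self.sigma2 is not None else ""),
        ]
        return "\n".join(lines)


class TTWModel:
    """Selection-bias-adjusted regression under homogeneous selection bias.

    Parameters
    ----------
    data : SelectionDataset
    bias_design : array, optional
        Design of the bias function delta; defaults to the outcome design.
    """

    def __init__(self, data: SelectionDataset, bias_design=None):
        self.data = data
        if bias_design is None:
            self.bias_design = data.outcome_design
        else:
            self.bias_design = np.asarray(bias_design, dtype=float)
            if self.bias_design.shape[0] != data.nobs:
                raise ValueError("bias_design row count mismatch")

    @classmethod
    def from_dataframe(cls, df, outcome, covariates, selection_instruments,
                       selected=None):
        return cls(SelectionDataset.from_dataframe(
            df, outcome, covariates, selection_instruments, selected))

    def loglike(self, params):
        return ttw_loglik(params, self.data, self.bias_design)

    # ------------------------------------------------------------------ #

    def _augmented_design(self, pi):
        """[X, (1-pi) * B] over selected rows, with a conditioning check."""
        d = self.data
        sel = d.selected
        A = np.hstack([d.outcome_design[sel],
                       (1.0 - pi[sel])[:, None] * self.bias_design[sel]])
        norms = np.linalg.norm(A, axis=0)
        if np.any(norms == 0):
            raise IdentificationError("augmented design has a zero column")
        cond = np.linalg.cond(A / norms)
        if cond > _COND_MAX:
            raise IdentificationError(
                "outcome and selection-bias terms are not separably "
                "estimable (near-singular Hessian); the selection "
                "instrument is too weak or absent from the propensity model")
        return A

    def fit(self, mode="partial", family="linear", maxiter=1000):
        if family == "linear":
            if mode == "partial":
                return self._fit_partial_linear()
            if mode == "full":
                return self._fit_full_linear(maxiter=maxiter)
            raise ValueError(f"unknown mode {mode!r}")
        if family in ("logistic", "poisson"):
            if mode != "partial":
                raise ValueError("logistic/poisson families support partial mode only")
            return self._fit_partial_glm(family)
        raise ValueError(f"unknown family {family!r}")

    def _fit_partial_linear(self):
        d = self.data
        prop = fit_propensity(d.selection_design, d.selected)
        pi = prop.fitted_pi
        A = self._augmented_design(pi)
        y = d.outcome[d.selected]
        coefs, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coefs
        n1 = d.n_selected
        sigma2 = float(resid @ resid / n1)   # MLE of sigma^2
        # Inverse negative Hessian of the stage-2 Gaussian log-likelihood:
        # the (coef, sigma2) cross-block vanishes at the optimum, so the
        # coefficient block is sigma2 * (A'A)^{-1}.
        cov = sigma2 * np.linalg.inv(A.T @ A)
        se = np.sqrt(np.diag(cov))
        p = d.n_outcome_params
        pb = self.bias_design.shape[1]
        params = np.concatenate([coefs, prop.alpha, [sigma2]])
        llf = self.loglike(params)
        return TTWResults(
            self, coefs[:p], se[:p], eta=coefs[p:p + pb], eta_se=se[p:p + pb],
            alpha_prop=prop.alpha, alpha_se=np.sqrt(np.diag(prop.cov)),
            sigma2=sigma2, llf=float(llf), mode="partial", family="linear",
        )

    def _fit_full_linear(self, maxiter=1000):
        d = self.data
        start_res = self._fit_partial_linear()
        p = d.n_outcome_params
        pb = self.bias_design.shape[1]
        q = d.n_selection_params
        x0 = np.concatenate([start_res.params, start_res.eta,
                             start_res.alpha_prop,
                             [np.log(start_res.sigma2)]])

        def neg(t):
            params = np.concatenate([t[:-1], [np.exp(t[-1])]])
            return -ttw_loglik(params, d, self.bias_design)

        res = optimize.minimize(neg, x0, method="BFGS",
                                options={"gtol": 1e-8, "maxiter": maxiter})
        if not res.success and np.linalg.norm(res.jac, np.inf) > 1e-4:
            raise ConvergenceError(f"TTW full optimization failed: {res.message}",
                                   trace=res)
        t = res.x
        sigma2 = float(np.exp(t[-1]))
        hess = approx_hess1(t, neg)
        eig = np.linalg.eigvalsh(hess)
        if eig.min() <= 0 or eig.max() / eig.min() > _COND_MAX:
            raise IdentificationError(
                "Hessian not positive definite at the optimum (flat "
                "likelihood; typically a weak instrument for selection)")
        cov_t = np.linalg.inv(hess)
        jac = np.ones(len(t))
        jac[-1] = sigma2
        cov = cov_t * np.outer(jac, jac)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        return TTWResults(
            self, t[:p], se[:p], eta=t[p:p + pb], eta_se=se[p:p + pb],
            alpha_prop=t[p + pb:p + pb + q], alpha_se=se[p + pb:p + pb + q],
            sigma2=sigma2, llf=float(-res.fun), mode="full", family="linear",
            converged=res.success,
        )

    def _fit_partial_glm(self, family):
        d = self.data
        sel = d.selected
        y = d.outcome[sel]
        if family == "logistic":
            if not np.all(np.isin(y, (0.0, 1.0))):
                raise ValueError("logistic family requires a 0/1 outcome")
            fam = sm.families.Binomial()
        else:
            if np.any(y < 0) or np.any(y != np.round(y)):
                raise ValueError("poisson family requires nonnegative integer outcomes")
            fam = sm.families.Poisson()
        prop = fit_propensity(d.selection_design, sel)
        A = self._augmented_design(prop.fitted_pi)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(y, A, family=fam).fit()
        if not np.all(np.isfinite(glm.bse)):
            raise IdentificationError("singular Hessian in GLM outcome stage")
        p = d.n_outcome_params
        pb = self.bias_design.shape[1]
        return TTWResults(
            self, glm.params[:p], glm.bse[:p],
            eta=glm.params[p:p + pb], eta_se=glm.bse[p:p + pb],
            alpha_prop=prop.alpha, alpha_se=np.sqrt(np.diag(prop.cov)),
            sigma2=None, llf=float(glm.llf + prop.llf), mode="partial",
            family=family,
        )


# Functional conveniences ------------------------------------------------- #

def ttw_fit_partial(data: SelectionDataset, bias_design=None) -> TTWResults:
    """Two-stage (partial-optimization) TTW fit for a continuous outcome."""
    return TTWModel(data, bias_design).fit(mode="partial")


def ttw_fit_full(data: SelectionDataset, bias_design=None) -> TTWResults:
    """Joint maximization over outcome, bias and propensity parameters."""
    return TTWModel(data, bias_design).fit(mode="full")


def ttw_fit_glm(data: SelectionDataset, family, bias_design=None) -> TTWResults:
    """Partial-optimization TTW fit for a binary or count outcome."""
    return TTWModel(data, bias_design).fit(mode="partial", family=family)
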