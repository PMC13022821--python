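"""Heckman's sample-selection model.

The model couples a linear outcome equation

    Y_i = X_i' beta + eps_i,                 eps_i ~ N(0, sigma1^2)

with a latent selection process

    Ytilde_i = Xtilde_i' gamma + epstilde_i, epstilde_i ~ N(0, 1)

where the outcome is observed iff Ytilde_i > 0 (a probit selection model;
the latent scale sigma2 is not identified and is fixed at 1) and the two
errors have covariance sigma12.  Selection on the latent scale induces

    E(Y | X, Ytilde > 0) = X' beta + sigma12 * lambda

with ``lambda`` the inverse Mills ratio evaluated at the probit index.  The
selection design must contain at least one instrument for selection Z that
is excluded from the outcome design; without it the Mills-ratio regressor
is close to collinear with X and the model is practically unidentified.

Estimation is by Heckman's two-step procedure (probit first stage, then
least squares of Y on [X, lambda-hat] with the classical covariance
correction for the estimated first stage) or by full-information maximum
likelihood on the bivariate-normal model.  A bivariate-probit variant
handles binary outcomes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
import statsmodels.api as sm
from statsmodels.tools.numdiff import approx_hess1
from statsmodels.tools.sm_exceptions import (PerfectSeparationError,
                                             PerfectSeparationWarning)

from .data import SelectionDataset
from .exceptions import (CollinearityError, ConvergenceError, FitError,
                         SeparationError)

__all__ = [
    "inverse_mills", "fit_probit", "bivariate_normal_cdf",
    "HeckmanSelectionModel", "HeckmanResults",
    "heckman_two_step", "heckman_ml", "heckman_binary_ml",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def inverse_mills(x):
    """Inverse Mills ratio ``phi(x) / (1 - Phi(x))``.

    Evaluated as ``exp(log phi(x) - log Phi(-x))`` so that it neither
    underflows to 0/0 nor overflows for large |x| (stable at least on
    |x| <= 40).  This is the hazard function of the standard normal; for a
    probit selection index ``a = Xtilde' gamma`` the correction regressor is
    ``inverse_mills(-a) = phi(a) / Phi(a)``.
    """
    x = np.asarray(x, dtype=float)
    log_phi = -0.5 * x ** 2 - _LOG_SQRT_2PI
    return np.exp(log_phi - special.log_ndtr(-x))


class ProbitFit:
    """First-stage probit: coefficients, covariance and log-likelihood."""

    def __init__(self, params, cov, llf, n_iter):
        self.params = np.asarray(params, dtype=float)
        self.cov = np.asarray(cov, dtype=float)
        self.llf = float(llf)
        self.n_iter = n_iter


def fit_probit(selection_design, selected, maxiter=100):
    """Probit regression of the selection indicator on the selection design.

    Returns a :class:`ProbitFit` with the MLE and the inverse observed
    information as covariance.  Raises :class:`SeparationError` on complete
    or quasi-complete separation and :class:`ConvergenceError` (carrying the
    iteration trace) if Newton iterations do not converge.
    """
    selection_design = np.asarray(selection_design, dtype=float)
    selected = np.asarray(selected).ravel().astype(int)
    if selected.min() == selected.max():
        raise SeparationError("selection indicator is constant; both classes required")
    if np.any(np.all(selection_design == 0.0, axis=0)):
        raise FitError("selection design contains an all-zero column")
    model = sm.Probit(selected, selection_design)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            warnings.simplefilter("error", category=PerfectSeparationWarning)
            try:
                res = model.fit(disp=0, maxiter=maxiter)
            except RuntimeWarning as w:  # singular information etc.
                raise SeparationError(f"probit fit failed: {w}") from w
    except (PerfectSeparationError, PerfectSeparationWarning) as err:
        raise SeparationError(f"perfect separation in probit fit: {err}") from err
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(
            f"probit did not converge in {maxiter} iterations",
            trace=res.mle_retvals,
        )
    if np.max(np.abs(res.params)) > 1e3:
        raise SeparationError("quasi-complete separation (diverging probit coefficients)")
    return ProbitFit(res.params, res.cov_params(), res.llf,
                     res.mle_retvals.get("iterations"))


def bivariate_normal_cdf(h, k, rho):
    """P(U <= h, V <= k) for standard bivariate normal (U, V) with
    correlation ``rho``, via Owen's T function.  Vectorized in h, k."""
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    if abs(rho) < 1e-12:
        return special.ndtr(h) * special.ndtr(k)
    if rho > 1 - 1e-12:
        return special.ndtr(np.minimum(h, k))
    if rho < -1 + 1e-12:
        return np.clip(special.ndtr(h) + special.ndtr(k) - 1.0, 0.0, 1.0)
    s = np.sqrt(1.0 - rho * rho)
    # guard exact zeros; the limit is approached smoothly
    hs = np.where(h == 0.0, 1e-300, h)
    ks = np.where(k == 0.0, 1e-300, k)
    ah = (k - rho * h) / (hs * s)
    ak = (h - rho * k) / (ks * s)
    hk = hs * ks
    beta = np.where((hk > 0) | ((hk == 0) & (h + k >= 0)), 0.0, 0.5)
    p = (0.5 * (special.ndtr(h) + special.ndtr(k))
         - special.owens_t(h, ah) - special.owens_t(k, ak) - beta)
    return np.clip(p, 0.0, 1.0)


class HeckmanResults:
    """Estimates from a Heckman sample-selection fit.

    Attributes
    ----------
    params, bse : outcome-equation coefficients beta and standard errors.
    gamma, gamma_se : probit selection coefficients (scale sigma2 = 1).
    rho_sigma : coefficient on the inverse Mills ratio (sigma12 = rho*sigma1).
    sigma1 : residual SD of the outcome equation.
    rho : error correlation.
    llf : log-likelihood (None for the two-step estimator).
    method : "two-step", "ml" or "binary-ml".
    """

    def __init__(self, model, params, bse, gamma, gamma_se, rho_sigma,
                 rho_sigma_se, sigma1, rho, llf, method, converged=True,
                 fit_warnings=(), extra=None):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.bse = np.asarray(bse, dtype=float)
        self.gamma = np.asarray(gamma, dtype=float)
        self.gamma_se = np.asarray(gamma_se, dtype=float)
        self.rho_sigma = rho_sigma
        self.rho_sigma_se = rho_sigma_se
        self.sigma1 = sigma1
        self.rho = rho
        self.llf = llf
        self.method = method
        self.converged = converged
        self.fit_warnings = list(fit_warnings)
        self.extra = extra or {}

    @property
    def tvalues(self):
        return self.params / self.bse

    def conf_int(self, alpha=0.05):
        z = stats.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - z * self.bse,
                                self.params + z * self.bse])

    def to_dict(self):
        """JSON-serializable summary of the fit."""
        return {
            "method": self.method,
            "beta": self.params.tolist(),
            "beta_se": self.bse.tolist(),
            "beta_names": list(self.model.data.outcome_names),
            "gamma": self.gamma.tolist(),
            "gamma_se": self.gamma_se.tolist(),
            "gamma_names": list(self.model.data.selection_names),
            "rho_sigma": self.rho_sigma,
            "sigma1": self.sigma1,
            "rho": self.rho,
            "loglik": self.llf,
            "converged": self.converged,
            "warnings": self.fit_warnings,
        }

    def summary(self):
        ci = self.conf_int()
        out = pd.DataFrame({
            "coef": self.params, "std err": self.bse, "z": self.tvalues,
            "[0.025": ci[:, 0], "0.975]": ci[:, 1],
        }, index=self.model.data.outcome_names)
        sel = pd.DataFrame({
            "coef": self.gamma, "std err": self.gamma_se,
        }, index=self.model.data.selection_names)
        lines = [
            "Heckman sample selection model",
            f"method: {self.method}   n = {self.model.data.nobs} "
            f"(selected {self.model.data.n_selected})",
            "",
            "Outcome equation:",
            out.to_string(float_format=lambda v: f"{v: .4f}"),
            "",
            "Selection equation (probit):",
            sel.to_string(float_format=lambda v: f"{v: .4f}"),
            "",
            f"rho_sigma (coef on Mills ratio): {self.rho_sigma:.4f}   "
            f"sigma1: {self.sigma1:.4f}   rho: {self.rho:.4f}",
        ]
        if self.llf is not None:
            lines.append(f"log-likelihood: {self.llf:.4f}")
        if self.fit_warnings:
            lines.append("warnings: " + "; ".join(self.fit_warnings))
        return "\n".join(lines)


class HeckmanSelectionModel:
    """Sample-selection model for a continuous (or binary) outcome.

    Parameters
    ----------
    data : SelectionDataset
        Outcome design, selection design (containing the instrument for
        selection), outcome with NaN for non-selected rows, and selection
        indicator.
    """

    def __init__(self, data: SelectionDataset):
        self.data = data

    @classmethod
    def from_dataframe(cls, df, outcome, covariates, selection_instruments,
                       selected=None):
        return cls(SelectionDataset.from_dataframe(
            df, outcome, covariates, selection_instruments, selected))

    # ------------------------------------------------------------------ #

    def fit(self, method="two-step", start=None, ols_se=False, maxiter=500):
        """Fit by ``"two-step"``, ``"ml"`` or ``"binary-ml"``."""
        if method in ("two-step", "two_step"):
            return self._fit_two_step(ols_se=ols_se)
        if method == "ml":
            return self._fit_ml(start=start, maxiter=maxiter)
        if method in ("binary-ml", "binary_ml"):
            return self._fit_binary_ml(maxiter=maxiter)
        raise ValueError(f"unknown method {method!r}")

    # -- two-step ------------------------------------------------------- #

    def _ols_fallback(self, message, method="two-step"):
        d = self.data
        sel = d.selected
        res = sm.OLS(d.outcome[sel], d.outcome_design[sel]).fit()
        warnings.warn(message)
        q = d.n_selection_params
        return HeckmanResults(
            self, res.params, res.bse,
            gamma=np.full(q, np.nan), gamma_se=np.full(q, np.nan),
            rho_sigma=0.0, rho_sigma_se=np.nan,
            sigma1=float(np.sqrt(res.scale)), rho=0.0, llf=None,
            method=method, fit_warnings=[message],
        )

    def _fit_two_step(self, ols_se=False):
        d = self.data
        sel = d.selected
        n1 = d.n_selected
        if n1 < d.n_outcome_params + 2:
            raise FitError("need at least p+2 selected individuals")
        if sel.all():
            return self._ols_fallback(
                "all individuals selected; the selection model is vacuous "
                "and an ordinary least-squares fit is returned")

        probit = fit_probit(d.selection_design, sel)
        a = d.selection_design @ probit.params          # probit index
        lam = inverse_mills(-a)                          # phi(a)/Phi(a)
        lam_s = lam[sel]
        X_s = d.outcome_design[sel]
        y_s = d.outcome[sel]

        # degenerate/collinear Mills ratio: project lambda on span(X)
        coef_proj, _, _, _ = np.linalg.lstsq(X_s, lam_s, rcond=None)
        resid_lam = lam_s - X_s @ coef_proj
        rel = np.linalg.norm(resid_lam) / max(np.linalg.norm(lam_s), 1e-300)
        if rel < 1e-10:
            return self._ols_fallback(
                "inverse Mills ratio is constant given the outcome design "
                "(no exclusion information); returning the OLS fit")
        if rel < 1e-6:
            raise CollinearityError(
                "inverse Mills ratio is numerically collinear with the "
                "outcome design; the instrument for selection Z adds no "
                "exclusion information")

        W = np.column_stack([X_s, lam_s])
        ols = sm.OLS(y_s, W).fit()
        coefs = ols.params
        beta = coefs[:-1]
        beta_lam = coefs[-1]
        e = y_s - W @ coefs

        a_s = a[sel]
        delta = lam_s * (lam_s + a_s)                    # in (0, 1)
        sigma2 = (e @ e + beta_lam ** 2 * delta.sum()) / n1
        sigma1 = float(np.sqrt(sigma2))
        rho = float(np.clip(beta_lam / sigma1, -1.0, 1.0))

        if ols_se:
            cov = ols.cov_params()
        else:
            # Heckman (1979) covariance: heteroskedastic residuals plus
            # first-stage uncertainty in gamma.
            rho2 = min(beta_lam ** 2 / sigma2, 1.0)
            WtW_inv = np.linalg.inv(W.T @ W)
            Xt_s = d.selection_design[sel]
            WdX = W.T @ (delta[:, None] * Xt_s)
            Q = rho2 * (WdX @ probit.cov @ WdX.T)
            mid = W.T @ ((1.0 - rho2 * delta)[:, None] * W) + Q
            cov = sigma2 * (WtW_inv @ mid @ WtW_inv)

        se = np.sqrt(np.diag(cov))
        return HeckmanResults(
            self, beta, se[:-1],
            gamma=probit.params, gamma_se=np.sqrt(np.diag(probit.cov)),
            rho_sigma=float(beta_lam), rho_sigma_se=float(se[-1]),
            sigma1=sigma1, rho=rho, llf=None, method="two-step",
            extra={"probit_llf": probit.llf},
        )

    # -- maximum likelihood --------------------------------------------- #

    def _pack(self, beta, gamma, sigma1, rho):
        return np.concatenate([beta, gamma,
                               [np.log(sigma1), np.arctanh(rho)]])

    def _unpack(self, params):
        p = self.data.n_outcome_params
        q = self.data.n_selection_params
        beta = params[:p]
        gamma = params[p:p + q]
        sigma1 = np.exp(params[p + q])
        rho = np.tanh(params[p + q + 1])
        return beta, gamma, sigma1, rho

    def loglike(self, params):
        """Bivariate-normal sample-selection log-likelihood at the packed
        parameter vector (beta, gamma, log sigma1, arctanh rho)."""
        d = self.data
        beta, gamma, sigma1, rho = self._unpack(params)
        u = d.selection_design @ gamma
        sel = d.selected
        ll_ns = special.log_ndtr(-u[~sel]).sum()
        z = (d.outcome[sel] - d.outcome_design[sel] @ beta) / sigma1
        s = np.sqrt(max(1.0 - rho * rho, 1e-12))
        ll_s = (-np.log(sigma1) - 0.5 * z ** 2 - _LOG_SQRT_2PI
                + special.log_ndtr((u[sel] + rho * z) / s)).sum()
        return ll_ns + ll_s

    def _fit_ml(self, start=None, maxiter=500):
        d = self.data
        if start is None:
            ts = self._fit_two_step(ols_se=True)
            if np.any(~np.isfinite(ts.gamma)):   # degenerate two-step
                raise FitError("two-step start values unavailable")
            rho0 = float(np.clip(ts.rho, -0.95, 0.95))
            start = self._pack(ts.params, ts.gamma, max(ts.sigma1, 1e-6), rho0)
        start = np.asarray(start, dtype=float)

        # minimize the *average* negative log-likelihood so that gradient
        # tolerances do not scale with n
        nobs = d.nobs
        neg_avg = lambda p: -self.loglike(p) / nobs
        res = optimize.minimize(neg_avg, start, method="BFGS",
                                options={"gtol": 1e-8, "maxiter": maxiter})
        if not res.success and np.linalg.norm(res.jac, np.inf) > 1e-5:
            raise ConvergenceError(
                f"Heckman ML did not converge: {res.message}", trace=res)
        beta, gamma, sigma1, rho = self._unpack(res.x)

        fit_warnings = []
        if abs(abs(rho) - 1.0) < 1e-6:
            fit_warnings.append("rho estimate on the boundary of (-1, 1)")

        hess = approx_hess1(res.x, neg_avg) * nobs
        try:
            cov_t = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov_t = np.linalg.pinv(hess)
        # delta method from (log sigma, arctanh rho) to (sigma, rho)
        p, q = d.n_outcome_params, d.n_selection_params
        jac = np.ones(p + q + 2)
        jac[p + q] = sigma1
        jac[p + q + 1] = 1.0 - rho ** 2
        cov = cov_t * np.outer(jac, jac)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))

        rho_sigma = float(rho * sigma1)
        return HeckmanResults(
            self, beta, se[:p], gamma=gamma, gamma_se=se[p:p + q],
            rho_sigma=rho_sigma, rho_sigma_se=np.nan,
            sigma1=float(sigma1), rho=float(rho),
            llf=float(-res.fun * nobs),
            method="ml", converged=res.success, fit_warnings=fit_warnings,
        )

    # -- binary outcome: bivariate probit with selection ----------------- #

    def _binary_loglike(self, params):
        d = self.data
        p = d.n_outcome_params
        q = d.n_selection_params
        beta = params[:p]
        gamma = params[p:p + q]
        rho = np.tanh(params[p + q])
        u = d.selection_design @ gamma
        sel = d.selected
        ll = special.log_ndtr(-u[~sel]).sum()
        xb = d.outcome_design[sel] @ beta
        y = d.outcome[sel]
        p11 = bivariate_normal_cdf(xb, u[sel], rho)
        p01 = bivariate_normal_cdf(-xb, u[sel], -rho)
        probs = np.where(y > 0.5, p11, p01)
        if np.any(probs <= 0):
            raise FitError("binary selection likelihood hit a zero-probability cell")
        return ll + np.log(probs).sum()

    def _fit_binary_ml(self, maxiter=500):
        d = self.data
        sel = d.selected
        y_s = d.outcome[sel]
        if not np.all(np.isin(y_s, (0.0, 1.0))):
            raise ValueError("binary-ml requires a 0/1 outcome on selected rows")
        out_probit = sm.Probit(y_s.astype(int), d.outcome_design[sel]).fit(disp=0)
        sel_probit = fit_probit(d.selection_design, sel)
        start = np.concatenate([out_probit.params, sel_probit.params, [0.0]])

        nobs = d.nobs
        neg = lambda pvec: -self._binary_loglike(pvec) / nobs
        res = optimize.minimize(neg, start, method="BFGS",
                                options={"gtol": 1e-8, "maxiter": maxiter})
        if not res.success and np.linalg.norm(res.jac, np.inf) > 1e-5:
            raise ConvergenceError(
                f"bivariate probit did not converge: {res.message}", trace=res)
        p, q = d.n_outcome_params, d.n_selection_params
        beta = res.x[:p]
        gamma = res.x[p:p + q]
        rho = float(np.tanh(res.x[p + q]))
        fit_warnings = []
        if abs(abs(rho) - 1.0) < 1e-6:
            fit_warnings.append("rho estimate on the boundary of (-1, 1)")
        hess = approx_hess1(res.x, neg) * nobs
        try:
            cov_t = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov_t = np.linalg.pinv(hess)
        jac = np.ones(p + q + 1)
        jac[p + q] = 1.0 - rho ** 2
        cov = cov_t * np.outer(jac, jac)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        return HeckmanResults(
            self, beta, se[:p], gamma=gamma, gamma_se=se[p:p + q],
            rho_sigma=rho, rho_sigma_se=float(se[p + q]),
            sigma1=1.0, rho=rho, llf=float(-res.fun * nobs),
            method="binary-ml",
            converged=res.success, fit_warnings=fit_warnings,
        )


# Functional conveniences ------------------------------------------------- #

def heckman_two_step(data: SelectionDataset, ols_se=False) -> HeckmanResults:
    """Two-step Heckman estimate on a :class:`SelectionDataset`."""
    return HeckmanSelectionModel(data).fit(method="two-step", ols_se=ols_se)


def heckman_ml(data: SelectionDataset, start=None) -> HeckmanResults:
    """Full-information ML Heckman estimate."""
    return HeckmanSelectionModel(data).fit(method="ml", start=start)


def heckman_binary_ml(data: SelectionDataset) -> HeckmanResults:
    """Bivariate-probit selection model for a binary outcome."""
    return HeckmanSelectionModel(data).fit(method="binary-ml")
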