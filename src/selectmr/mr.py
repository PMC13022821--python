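"""Mendelian randomization estimators with pluggable selection adjustment.

Causal effects are estimated by the Wald ratio (single instrument),
two-stage least squares (one-sample, multiple instruments) or the
inverse-variance-weighted combination of per-variant summary statistics
(two-sample).  Each constituent regression — the G-X association, the G-Y
association, or a 2SLS stage — can be replaced by a selection-adjusted fit
(Heckman or TTW) when the corresponding variable is missing not at random,
with the selection design always [1, G, Z] (the instrument for selection Z
is excluded from the outcome design).  Analytic 2SLS standard errors are
only valid without adjustment; with adjustment the standard error comes
from a nonparametric bootstrap over individuals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import MRDataset, SelectionDataset
from .exceptions import BootstrapError, ContractViolationError, SelectMRError
from .heckman import heckman_two_step
from .ttw import ttw_fit_partial

__all__ = ["MREstimate", "SummaryStats", "wald_ratio", "estimate_association",
           "mr_wald", "tsls", "tsls_bootstrap_se", "per_variant_summary_stats",
           "ivw"]

logger = logging.getLogger(__name__)

_ADJUSTERS = {"heckman": heckman_two_step, "ttw": ttw_fit_partial}


@dataclass
class MREstimate:
    """A causal effect estimate theta with its standard error.

    ``adjustment`` records which stage (if any) was selection-adjusted and
    how; ``n_boot`` is set when the SE comes from a bootstrap.
    """

    theta: float
    theta_se: float
    method: str
    adjustment: dict = field(default_factory=dict)
    n_boot: int | None = None
    n_failed_boot: int = 0

    @property
    def ci95(self):
        half = 1.96 * self.theta_se
        return (self.theta - half, self.theta + half)

    def to_dict(self):
        return {"theta": self.theta, "theta_se": self.theta_se,
                "method": self.method, "adjustment": self.adjustment,
                "n_boot": self.n_boot, "ci95": list(self.ci95)}


@dataclass
class SummaryStats:
    """Per-variant association estimates for the exposure and outcome."""

    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    adjustment: dict = field(default_factory=lambda: {"exposure": "none",
                                                      "outcome": "none"})
    one_sample: bool = False

    def __post_init__(self):
        self.beta_x = np.atleast_1d(np.asarray(self.beta_x, dtype=float))
        self.se_x = np.atleast_1d(np.asarray(self.se_x, dtype=float))
        self.beta_y = np.atleast_1d(np.asarray(self.beta_y, dtype=float))
        self.se_y = np.atleast_1d(np.asarray(self.se_y, dtype=float))
        if not (self.beta_x.size == self.se_x.size == self.beta_y.size
                == self.se_y.size):
            raise ValueError("summary-statistic vectors must share a length")
        if self.beta_x.size == 0:
            raise ValueError("empty summary statistics")
        if np.any(self.se_x <= 0) or np.any(self.se_y <= 0):
            raise ValueError("standard errors must be positive")

    @property
    def n_variants(self):
        return self.beta_x.size

    def to_frame(self):
        return pd.DataFrame({
            "variant": [f"g{j + 1}" for j in range(self.n_variants)],
            "beta_x": self.beta_x, "se_x": self.se_x,
            "beta_y": self.beta_y, "se_y": self.se_y,
        })

    @classmethod
    def from_frame(cls, df):
        return cls(df["beta_x"].to_numpy(), df["se_x"].to_numpy(),
                   df["beta_y"].to_numpy(), df["se_y"].to_numpy())


def wald_ratio(beta_x, se_x, beta_y, se_y) -> MREstimate:
    """Wald ratio theta = beta_y / beta_x with the second-order SE

    se = sqrt(se_y^2 / beta_x^2 + beta_y^2 se_x^2 / beta_x^4).
    """
    if beta_x == 0:
        raise ZeroDivisionError(
            "beta_x is zero: the genetic instrument has zero strength")
    theta = beta_y / beta_x
    se = np.sqrt(se_y ** 2 / beta_x ** 2
                 + beta_y ** 2 * se_x ** 2 / beta_x ** 4)
    return MREstimate(float(theta), float(se), method="wald")


def _univariate_ols(y, g):
    """Slope and SE of y on [1, g] over finite rows."""
    res = sm.OLS(y, sm.add_constant(g)).fit()
    return float(res.params[1]), float(res.bse[1])


def estimate_association(dataset: MRDataset, side, adjust="none",
                         per_variant=False):
    """Association of one side (exposure or outcome) with the instruments G.

    With ``adjust="none"`` the masked rows are simply dropped (complete-case
    OLS).  With ``adjust`` set to ``"heckman"`` or ``"ttw"`` and the side
    masked, the regression is replaced by the corresponding selection model
    with outcome design [1, G] and selection design [1, G, Z].  Returns
    ``(beta, se)``: scalars for a joint fit with K=1, arrays for
    ``per_variant=True`` or K>1.
    """
    if side not in ("exposure", "outcome"):
        raise ValueError("side must be 'exposure' or 'outcome'")
    values = dataset.exposure if side == "exposure" else dataset.outcome
    masked = bool(np.any(~np.isfinite(values)))
    if adjust not in ("none", "heckman", "ttw"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    if adjust != "none" and not masked:
        warnings.warn(f"{side} is fully observed; selection adjustment is "
                      "vacuous, falling back to OLS")
        adjust = "none"

    if per_variant:
        K = dataset.n_instruments
        betas = np.empty(K)
        ses = np.empty(K)
        for j in range(K):
            b, s = _one_association(
                values, dataset.instruments[:, j:j + 1],
                dataset.selection_instrument, dataset.selected, adjust)
            betas[j], ses[j] = b[0], s[0]
        return betas, ses
    beta, se = _one_association(values, dataset.instruments,
                                dataset.selection_instrument,
                                dataset.selected, adjust)
    if dataset.n_instruments == 1:
        return float(beta[0]), float(se[0])
    return beta, se


def _one_association(values, g, z, selected, adjust):
    """Coefficients on the columns of g (vectorized over K columns)."""
    if adjust == "none":
        keep = np.isfinite(values)
        res = sm.OLS(values[keep], sm.add_constant(g[keep], prepend=True)).fit()
        return np.atleast_1d(res.params[1:]), np.atleast_1d(res.bse[1:])
    n = values.size
    ones = np.ones((n, 1))
    sd = SelectionDataset(
        outcome_design=np.hstack([ones, g]),
        selection_design=np.hstack([ones, g, np.asarray(z, float).reshape(n, 1)]),
        outcome=values, selected=selected,
    )
    fit = _ADJUSTERS[adjust](sd)
    return fit.params[1:], fit.bse[1:]


def mr_wald(dataset: MRDataset, adjust_exposure="none",
            adjust_outcome="none") -> MREstimate:
    """Wald-ratio causal estimate with per-side selection adjustment.

    Requires a single instrument for inference (K=1, e.g. an allele score).
    """
    if dataset.n_instruments != 1:
        raise ValueError("the Wald ratio requires a single instrument; "
                         "combine variants into a score first")
    bx, sx = estimate_association(dataset, "exposure", adjust_exposure)
    by, sy = estimate_association(dataset, "outcome", adjust_outcome)
    est = wald_ratio(bx, sx, by, sy)
    est.adjustment = {"exposure": adjust_exposure, "outcome": adjust_outcome}
    return est


# -- two-stage least squares ---------------------------------------------- #

def _tsls_point(dataset: MRDataset, adjust_first, adjust_second):
    """2SLS point estimate with optional per-stage selection adjustment."""
    g = dataset.instruments
    z = dataset.selection_instrument
    r = dataset.selected
    n = dataset.nobs
    ones = np.ones((n, 1))
    G1 = np.hstack([ones, g])

    x_masked = dataset.exposure_masked()
    y_masked = dataset.outcome_masked()

    if adjust_first == "none" and adjust_second == "none":
        # complete-case 2SLS: drop rows missing in any variable of either stage
        keep = np.isfinite(dataset.exposure) & np.isfinite(dataset.outcome)
        x, y, Gk = dataset.exposure[keep], dataset.outcome[keep], G1[keep]
        coef1, _, _, _ = np.linalg.lstsq(Gk, x, rcond=None)
        xhat = Gk @ coef1
        W = np.column_stack([np.ones(keep.sum()), xhat])
        coef2, _, _, _ = np.linalg.lstsq(W, y, rcond=None)
        theta = coef2[1]
        # analytic SE: second-stage design with residuals from the original x
        resid = y - coef2[0] - theta * x
        sigma2 = resid @ resid / (keep.sum() - 2)
        cov = sigma2 * np.linalg.inv(W.T @ W)
        return float(theta), float(np.sqrt(cov[1, 1]))

    # stage 1: G-X associations, selection-adjusted if the exposure is masked
    if x_masked and adjust_first != "none":
        sd1 = SelectionDataset(
            outcome_design=G1,
            selection_design=np.hstack([G1, z[:, None]]),
            outcome=dataset.exposure, selected=r)
        fit1 = _ADJUSTERS[adjust_first](sd1)
        xhat = G1 @ fit1.params
    else:
        keep = np.isfinite(dataset.exposure)
        res1 = sm.OLS(dataset.exposure[keep], G1[keep]).fit()
        xhat = G1 @ res1.params        # fitted values for every individual

    # stage 2: Y on fitted exposure, adjusted if the outcome is masked
    W = np.hstack([ones, xhat[:, None]])
    if y_masked and adjust_second != "none":
        sd2 = SelectionDataset(
            outcome_design=W,
            selection_design=np.hstack([W, z[:, None]]),
            outcome=dataset.outcome, selected=r)
        fit2 = _ADJUSTERS[adjust_second](sd2)
        theta = fit2.params[1]
    else:
        keep = np.isfinite(dataset.outcome)
        res2 = sm.OLS(dataset.outcome[keep], W[keep]).fit()
        theta = res2.params[1]
    return float(theta), None


def tsls(dataset: MRDataset, adjust_first="none", adjust_second="none",
         boot=None, seed=None) -> MREstimate:
    """Two-stage least squares with optional selection adjustment.

    Without adjustment the analytic standard error of the second stage
    (computed with residuals from the original exposure) is reported.  With
    a selection-adjusted stage the analytic formula is invalid; pass
    ``boot=M`` to obtain a bootstrap SE, otherwise the SE is NaN.
    """
    adjusted = adjust_first != "none" or adjust_second != "none"
    theta, se = _tsls_point(dataset, adjust_first, adjust_second)
    est = MREstimate(theta, np.nan if se is None else se, method="tsls",
                     adjustment={"first": adjust_first, "second": adjust_second})
    if adjusted and boot is not None:
        bse, n_failed = tsls_bootstrap_se(dataset, adjust_first, adjust_second,
                                          M=boot, seed=seed)
        est.theta_se = bse
        est.n_boot = boot
        est.n_failed_boot = n_failed
    return est


def tsls_analytic_se_guard(adjust_first, adjust_second):
    """Raise if an analytic 2SLS SE is requested with adjustment active."""
    if adjust_first != "none" or adjust_second != "none":
        raise ContractViolationError(
            "the analytic 2SLS standard-error formula cannot be used in "
            "conjunction with selection-adjusted stages; use the bootstrap")


def tsls_bootstrap_se(dataset: MRDataset, adjust_first, adjust_second,
                      M=100, seed=None):
    """Bootstrap SE of the (adjusted) 2SLS estimate.

    Resamples individuals with replacement M times, reruns the full
    adjusted 2SLS on each resample and returns ``(sd, n_failed)`` over the
    successful resamples.  More than 20% failures raises
    :class:`BootstrapError`.
    """
    if M < 2:
        raise ValueError("need at least two bootstrap resamples")
    rng = np.random.default_rng(seed)
    n = dataset.nobs
    thetas = []
    n_failed = 0
    for _ in range(M):
        idx = rng.integers(0, n, size=n)
        sample = MRDataset(
            instruments=dataset.instruments[idx],
            exposure=dataset.exposure[idx], outcome=dataset.outcome[idx],
            selection_instrument=dataset.selection_instrument[idx],
            selected=dataset.selected[idx])
        try:
            theta, _ = _tsls_point(sample, adjust_first, adjust_second)
            thetas.append(theta)
        except SelectMRError:
            n_failed += 1
    if n_failed > 0.2 * M:
        raise BootstrapError(
            f"{n_failed}/{M} bootstrap resamples failed; SE unreliable")
    return float(np.std(thetas, ddof=1)), n_failed


# -- summary statistics and IVW ------------------------------------------- #

def per_variant_summary_stats(exposure_data: MRDataset,
                              outcome_data: MRDataset | None = None,
                              adjust_exposure="none",
                              adjust_outcome="none") -> SummaryStats:
    """Per-variant association estimates, one univariate regression per
    variant and side, each optionally selection-adjusted.

    With ``outcome_data`` given, exposure associations come from
    ``exposure_data`` and outcome associations from ``outcome_data``
    (two-sample design); otherwise both come from the single dataset.
    """
    one_sample = outcome_data is None
    if one_sample:
        outcome_data = exposure_data
    if exposure_data.n_instruments != outcome_data.n_instruments:
        raise ValueError("instrument count mismatch between samples")
    bx, sx = estimate_association(exposure_data, "exposure",
                                  adjust_exposure, per_variant=True)
    by, sy = estimate_association(outcome_data, "outcome",
                                  adjust_outcome, per_variant=True)
    return SummaryStats(bx, sx, by, sy,
                        adjustment={"exposure": adjust_exposure,
                                    "outcome": adjust_outcome},
                        one_sample=one_sample)


def ivw(stats: SummaryStats, se_mode="second_order") -> MREstimate:
    """Inverse-variance-weighted causal estimate from summary statistics.

    First-order weights are 1/se_y^2.  ``second_order`` re-weights once by
    1/(se_y^2 + theta1^2 se_x^2) with theta1 the first-order estimate.
    """
    if stats.n_variants == 0:
        raise ValueError("empty summary statistics")
    if stats.one_sample:
        logger.warning(
            "IVW applied to one-sample summary statistics: overlapping "
            "samples exacerbate weak-instrument bias; interpret with caution")
    bx, by = stats.beta_x, stats.beta_y
    w = stats.se_y ** -2
    theta = float(np.sum(bx * by * w) / np.sum(bx ** 2 * w))
    if se_mode == "second_order":
        w = 1.0 / (stats.se_y ** 2 + theta ** 2 * stats.se_x ** 2)
        theta = float(np.sum(bx * by * w) / np.sum(bx ** 2 * w))
    elif se_mode != "first_order":
        raise ValueError(f"unknown se_mode {se_mode!r}")
    se = float(np.sqrt(1.0 / np.sum(bx ** 2 * w)))
    return MREstimate(theta, se, method="ivw",
                      adjustment=dict(stats.adjustment))
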