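"""Monte-Carlo engine: generative scenarios, missingness tuning, and the
replication runner.

Two families of generative models are provided.  The regression family
draws a covariate X, an instrument for selection Z and an outcome Y
(continuous, binary or Poisson), and masks Y through a logistic selection
model  logit pi_R = alpha_R + beta_R X + gamma_R Z + delta_R Y.  The MR
family draws genetic instruments G (a single normally distributed score,
or K allele-count variants), a confounder U, exposure X and outcome Y, and
masks X and/or Y through the same kind of logistic selection model.  The
selection intercept alpha_R is tuned by stochastic root-finding so that
the target fraction of individuals (default 50%) is selected.

Note the deliberate working-model mismatch: data are always selected
through a *logistic* model while the Heckman estimator assumes a probit
selection equation.  This mismatch is part of the study conditions and
must not be removed.

``run_replications`` executes a scenario for many independent replications
and reports, per estimator: the mean estimate, the empirical SD across
replications, the mean model-based SE, the empirical coverage of 95%
confidence intervals, and the empirical power to reject a zero effect
(the type-I error rate when the true effect is zero).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

from . import baselines, mr
from .data import MRDataset, SelectionDataset
from .exceptions import SelectMRError
from .heckman import heckman_binary_ml, heckman_two_step
from .ttw import TTWModel, fit_propensity

__all__ = ["RegressionScenario", "MRScenario", "regression_scenario",
           "mr_scenario", "scenario_from_dict", "tune_alpha_R",
           "gen_regression", "gen_mr", "run_replications",
           "SimulationResult", "REGRESSION_VARIANTS", "MR_SELECTION_MODES"]

logger = logging.getLogger(__name__)

_TUNE_SALT = 714025          # fixed offset separating the tuning stream
BETA_X_SINGLE = np.sqrt(2.0 / 19.0)   # G explains 5% of var(X) exactly

REGRESSION_VARIANTS = ("baseline", "null_beta", "binary_Z", "binary_X",
                       "binary_Y", "poisson_Y", "no_XR", "no_YR",
                       "ZX_effect", "ZY_effect")
MR_SELECTION_MODES = ("y", "x", "xy")


@dataclass(frozen=True)
class RegressionScenario:
    """One regression simulation setting.

    Defaults are the baseline study conditions: slope beta = 0.1,
    intercept alpha = 1, instrument-selection effect gamma_R = 0.4
    (about 2% of selection variation), covariate and outcome selection
    effects beta_R = delta_R = 0.5, n = 10^4, ~50% of outcomes missing.
    """

    beta: float = 0.1
    alpha: float = 1.0
    gamma_R: float = 0.4
    beta_R: float = 0.5
    delta_R: float = 0.5
    alpha_R: float | str = "auto"
    n: int = 10_000
    variant: str = "baseline"
    beta_XZ: float | None = None     # ZX_effect only
    gamma_ZY: float | None = None    # ZY_effect only

    def __post_init__(self):
        if self.variant not in REGRESSION_VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; "
                             f"valid: {REGRESSION_VARIANTS}")
        if (self.beta_XZ is not None) != (self.variant == "ZX_effect"):
            raise ValueError("beta_XZ is specific to the ZX_effect variant")
        if (self.gamma_ZY is not None) != (self.variant == "ZY_effect"):
            raise ValueError("gamma_ZY is specific to the ZY_effect variant")

    @property
    def family(self):
        return {"binary_Y": "logistic", "poisson_Y": "poisson"}.get(
            self.variant, "linear")

    @property
    def truth(self):
        return self.beta


def regression_scenario(name, **overrides) -> RegressionScenario:
    """Named scenario constructor covering every studied variant."""
    presets = {
        "baseline": {},
        "null_beta": {"beta": 0.0, "variant": "null_beta"},
        "binary_Z": {"variant": "binary_Z"},
        "binary_X": {"variant": "binary_X"},
        "binary_Y": {"variant": "binary_Y"},
        "poisson_Y": {"variant": "poisson_Y"},
        "no_XR": {"beta_R": 0.0, "variant": "no_XR"},
        "no_YR": {"delta_R": 0.0, "variant": "no_YR"},
        "ZX_effect": {"beta_XZ": 1.0 / 3.0, "variant": "ZX_effect"},
        "ZY_effect": {"gamma_ZY": 1.0 / 3.0, "variant": "ZY_effect"},
    }
    if name not in presets:
        raise KeyError(f"unknown scenario {name!r}; valid: {sorted(presets)}")
    kw = dict(presets[name])
    kw.update(overrides)
    return RegressionScenario(**kw)


@dataclass(frozen=True)
class MRScenario:
    """One Mendelian randomization simulation setting.

    ``selection`` names which variables drive selection and are masked:
    "y" (beta_R=0, delta_R=1), "x" (beta_R=1, delta_R=0) or "xy"
    (beta_R=delta_R=0.5).  K=1 uses a normally distributed allele score
    explaining 5% of the exposure variance; K>1 draws biallelic variants
    with frequencies U(0.1, 0.9) and effects from N(0, 0.05^2) left-
    truncated at 0.15.
    """

    theta: float = 0.2
    K: int = 1
    selection: str = "xy"
    gamma_X: float = 1.0
    gamma_Y: float = 1.0
    gamma_R: float = 0.5
    alpha_R: float | str = "auto"
    n: int = 10_000
    design: str = "one_sample"

    def __post_init__(self):
        if self.selection not in MR_SELECTION_MODES:
            raise ValueError(f"selection must be one of {MR_SELECTION_MODES}")
        if self.design not in ("one_sample", "two_sample"):
            raise ValueError("design must be 'one_sample' or 'two_sample'")

    @property
    def beta_R(self):
        return {"y": 0.0, "x": 1.0, "xy": 0.5}[self.selection]

    @property
    def delta_R(self):
        return {"y": 1.0, "x": 0.0, "xy": 0.5}[self.selection]

    @property
    def mask_exposure(self):
        return self.beta_R != 0.0

    @property
    def mask_outcome(self):
        return self.delta_R != 0.0

    @property
    def truth(self):
        return self.theta


def mr_scenario(selection, **overrides) -> MRScenario:
    return MRScenario(selection=selection, **overrides)


def scenario_from_dict(spec: dict):
    """Build a scenario from a key/value document (e.g. parsed YAML).

    ``kind`` selects "regression" or "mr"; the remaining keys are scenario
    fields.  Unknown keys are rejected.
    """
    spec = dict(spec)
    kind = spec.pop("kind", "regression")
    if kind == "regression":
        cls = RegressionScenario
    elif kind == "mr":
        cls = MRScenario
    else:
        raise ValueError(f"unknown scenario kind {kind!r}")
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(spec) - valid
    if unknown:
        raise ValueError(f"unknown scenario key(s) {sorted(unknown)}; "
                         f"valid: {sorted(valid)}")
    return cls(**spec)


# --------------------------------------------------------------------- #
# generation

def _draw_regression(scenario: RegressionScenario, rng, n):
    """Draw (Z, X, Y) for a regression scenario before selection."""
    s = scenario
    z = (rng.binomial(1, 0.5, n).astype(float) if s.variant == "binary_Z"
         else rng.standard_normal(n))
    if s.variant == "binary_X":
        x = rng.binomial(1, 0.5, n).astype(float)
    elif s.variant == "ZX_effect":
        x = s.beta_XZ * z + rng.standard_normal(n)
    else:
        x = rng.standard_normal(n)
    lin = s.alpha + s.beta * x
    if s.variant == "binary_Y":
        y = rng.binomial(1, special.expit(lin)).astype(float)
    elif s.variant == "poisson_Y":
        y = rng.poisson(np.exp(lin)).astype(float)
    elif s.variant == "ZY_effect":
        y = lin + s.gamma_ZY * z + rng.standard_normal(n)
    else:
        y = lin + rng.standard_normal(n)
    return z, x, y


def _draw_mr(scenario: MRScenario, rng, n):
    """Draw (G, Z, X, Y) for an MR scenario before selection."""
    s = scenario
    z = rng.standard_normal(n)
    u = rng.standard_normal(n)
    if s.K == 1:
        g = rng.standard_normal((n, 1))
        bx = np.array([BETA_X_SINGLE])
    else:
        f = rng.uniform(0.1, 0.9, s.K)
        g = rng.binomial(2, f, size=(n, s.K)).astype(float)
        # N(0, 0.05^2) left-truncated at 0.15
        bx = stats.truncnorm.rvs(0.15 / 0.05, np.inf, loc=0.0, scale=0.05,
                                 size=s.K, random_state=rng)
    x = g @ bx + s.gamma_X * u + rng.standard_normal(n)
    y = s.theta * x + s.gamma_Y * u + rng.standard_normal(n)
    return g, z, x, y


def _selection_linpred_regression(scenario, z, x, y):
    return scenario.beta_R * x + scenario.gamma_R * z + scenario.delta_R * y


def tune_alpha_R(scenario, target=0.5, tol=0.005, seed=0, pilot_n=1_000_000):
    """Selection-model intercept giving marginal P(R=1) ~= target.

    Root-finds on the Monte-Carlo marginal selection probability of a pilot
    sample (deterministic given ``seed``).  With all selection slopes zero
    the closed form logit(target) is returned exactly.
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target must lie in (0, 1)")
    s = scenario
    if s.beta_R == 0.0 and s.gamma_R == 0.0 and s.delta_R == 0.0:
        return float(special.logit(target))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _TUNE_SALT]))
    if isinstance(s, RegressionScenario):
        z, x, y = _draw_regression(s, rng, pilot_n)
        lin = _selection_linpred_regression(s, z, x, y)
    else:
        g, z, x, y = _draw_mr(s, rng, pilot_n)
        lin = s.beta_R * x + s.gamma_R * z + s.delta_R * y

    def objective(a):
        return special.expit(a + lin).mean() - target

    lo, hi = -2.0, 2.0
    while objective(lo) > 0:
        lo *= 2
        if lo < -60:
            raise SelectMRError("no sign change on the tuning bracket")
    while objective(hi) < 0:
        hi *= 2
        if hi > 60:
            raise SelectMRError("no sign change on the tuning bracket")
    root = optimize.brentq(objective, lo, hi, xtol=1e-8)
    if abs(objective(root)) > tol:
        raise SelectMRError("intercept tuning did not reach the tolerance")
    return float(root)


def resolve_alpha_R(scenario, seed=0):
    """Scenario with a numeric selection intercept (tuned if 'auto')."""
    if scenario.alpha_R == "auto":
        return replace(scenario, alpha_R=tune_alpha_R(scenario, seed=seed))
    return scenario


def gen_regression(scenario: RegressionScenario, seed=None, rng=None):
    """One simulated regression dataset.

    Returns a dict with the masked :class:`SelectionDataset` (``data``),
    the pre-masking outcome (``full_outcome``), the realized selection
    indicator, the outcome family and the true slope.
    """
    s = resolve_alpha_R(scenario, seed=0 if seed is None else seed)
    if rng is None:
        rng = np.random.default_rng(seed)
    n = s.n
    z, x, y = _draw_regression(s, rng, n)
    lin = s.alpha_R + _selection_linpred_regression(s, z, x, y)
    r = rng.random(n) < special.expit(lin)
    y_obs = np.where(r, y, np.nan)
    ones = np.ones((n, 1))
    data = SelectionDataset(
        outcome_design=np.column_stack([ones, x]),
        selection_design=np.column_stack([ones, x, z]),
        outcome=y_obs, selected=r,
        outcome_names=["const", "x"],
        selection_names=["const", "x", "z"],
    )
    return {"data": data, "full_outcome": y, "selected": r,
            "family": s.family, "truth": s.truth, "scenario": s}


def _gen_mr_sample(s: MRScenario, rng, mask_exposure, mask_outcome):
    n = s.n
    g, z, x, y = _draw_mr(s, rng, n)
    lin = s.alpha_R + s.beta_R * x + s.gamma_R * z + s.delta_R * y
    apply_selection = mask_exposure or mask_outcome
    if apply_selection:
        r = rng.random(n) < special.expit(lin)
    else:
        r = np.ones(n, dtype=bool)
    data = MRDataset(
        instruments=g,
        exposure=np.where(r, x, np.nan) if mask_exposure else x,
        outcome=np.where(r, y, np.nan) if mask_outcome else y,
        selection_instrument=z, selected=r)
    oracle = MRDataset(instruments=g, exposure=x, outcome=y,
                       selection_instrument=z,
                       selected=np.ones(n, dtype=bool))
    return data, oracle


def gen_mr(scenario: MRScenario, seed=None, rng=None):
    """One simulated MR dataset (or a pair, for the two-sample design).

    One-sample: ``data`` is a masked :class:`MRDataset` and ``oracle`` the
    pre-masking copy.  Two-sample: ``data``/``oracle`` are
    (exposure-sample, outcome-sample) pairs; selection applies only in the
    sample(s) whose measured variable drives selection.
    """
    s = resolve_alpha_R(scenario, seed=0 if seed is None else seed)
    if rng is None:
        rng = np.random.default_rng(seed)
    if s.design == "one_sample":
        data, oracle = _gen_mr_sample(s, rng, s.mask_exposure, s.mask_outcome)
        return {"data": data, "oracle": oracle, "truth": s.truth, "scenario": s}
    data_x, oracle_x = _gen_mr_sample(s, rng, s.mask_exposure, False)
    data_y, oracle_y = _gen_mr_sample(s, rng, False, s.mask_outcome)
    return {"data": (data_x, data_y), "oracle": (oracle_x, oracle_y),
            "truth": s.truth, "scenario": s}


# --------------------------------------------------------------------- #
# estimator arms

def _ttw_family_fit(data, family):
    mode = {"linear": ("partial", "linear"),
            "logistic": ("partial", "logistic"),
            "poisson": ("partial", "poisson")}[family]
    return TTWModel(data).fit(mode=mode[0], family=mode[1])


def _regression_estimate(method, rep, ipw_weight_design=None):
    """(estimate, SE) of the slope for one regression replication."""
    data = rep["data"]
    family = rep["family"]
    if method == "cca":
        fit = baselines.cca_fit(data, family=family)
    elif method == "ipw":
        fit = baselines.ipw_fit(data, weight_design=ipw_weight_design,
                                family=family)
    elif method == "oracle":
        fit = baselines.oracle_fit(data.outcome_design, rep["full_outcome"],
                                   family=family)
    elif method == "heckman":
        if family == "poisson":
            raise ValueError("Heckman's model has no Poisson variant")
        if family == "logistic":
            fit = heckman_binary_ml(data)
        else:
            fit = heckman_two_step(data)
    elif method == "ttw":
        fit = _ttw_family_fit(data, family)
    else:
        raise KeyError(f"unknown regression method {method!r}")
    return float(fit.params[1]), float(fit.bse[1])


def _ipw_side(dataset: MRDataset, side):
    """IPW-weighted association of one side with G.

    The weight model is logistic in G plus whichever of X/Y is fully
    observed (never the masked variable itself, never Z).
    """
    values = dataset.exposure if side == "exposure" else dataset.outcome
    other = dataset.outcome if side == "exposure" else dataset.exposure
    g = dataset.instruments
    design = sm.add_constant(g, prepend=True)
    if not np.any(~np.isfinite(values)):
        res = sm.OLS(values, design).fit()
        return float(res.params[1]), float(res.bse[1])
    wdesign = design
    if not np.any(~np.isfinite(other)):
        wdesign = np.column_stack([design, other])
    prop = fit_propensity(wdesign, dataset.selected)
    sel = dataset.selected
    w = 1.0 / prop.fitted_pi[sel]
    res = sm.WLS(values[sel], design[sel], weights=w).fit(cov_type="HC0")
    return float(res.params[1]), float(res.bse[1])


def _mr_wald_estimate(method, rep):
    data, oracle = rep["data"], rep["oracle"]
    if method == "oracle":
        est = mr.mr_wald(oracle)
    elif method == "cca":
        est = mr.mr_wald(data)
    elif method in ("heckman", "ttw"):
        adj_x = method if data.exposure_masked() else "none"
        adj_y = method if data.outcome_masked() else "none"
        est = mr.mr_wald(data, adjust_exposure=adj_x, adjust_outcome=adj_y)
    elif method == "ipw":
        bx, sx = _ipw_side(data, "exposure")
        by, sy = _ipw_side(data, "outcome")
        est = mr.wald_ratio(bx, sx, by, sy)
    else:
        raise KeyError(f"unknown MR method {method!r}")
    return est.theta, est.theta_se


def _mr_tsls_estimate(method, rep, boot_M, rng):
    data, oracle = rep["data"], rep["oracle"]
    if method == "oracle":
        est = mr.tsls(oracle)
    elif method == "cca":
        est = mr.tsls(data)
    elif method in ("heckman", "ttw"):
        adj1 = method if data.exposure_masked() else "none"
        adj2 = method if data.outcome_masked() else "none"
        seed = int(rng.integers(0, 2 ** 31 - 1)) if boot_M else None
        est = mr.tsls(data, adjust_first=adj1, adjust_second=adj2,
                      boot=boot_M if boot_M else None, seed=seed)
    else:
        raise KeyError(f"unknown 2SLS method {method!r}")
    return est.theta, est.theta_se


def _mr_ivw_estimate(method, rep):
    data, oracle = rep["data"], rep["oracle"]
    two_sample = isinstance(data, tuple)
    dx, dy = (data if two_sample else (data, data))
    ox, oy = (oracle if two_sample else (oracle, oracle))
    if method == "oracle":
        stats_ = mr.per_variant_summary_stats(ox, oy if two_sample else None)
    elif method == "cca":
        stats_ = mr.per_variant_summary_stats(dx, dy if two_sample else None)
    elif method in ("heckman", "ttw"):
        adj_x = method if dx.exposure_masked() else "none"
        adj_y = method if dy.outcome_masked() else "none"
        stats_ = mr.per_variant_summary_stats(
            dx, dy if two_sample else None,
            adjust_exposure=adj_x, adjust_outcome=adj_y)
    elif method == "ipw":
        K = dx.n_instruments
        bx = np.empty(K); sx = np.empty(K)
        by = np.empty(K); sy = np.empty(K)
        for j in range(K):
            sub_x = MRDataset(dx.instruments[:, j:j + 1], dx.exposure,
                              dx.outcome, dx.selection_instrument, dx.selected)
            sub_y = MRDataset(dy.instruments[:, j:j + 1], dy.exposure,
                              dy.outcome, dy.selection_instrument, dy.selected)
            bx[j], sx[j] = _ipw_side(sub_x, "exposure")
            by[j], sy[j] = _ipw_side(sub_y, "outcome")
        stats_ = mr.SummaryStats(bx, sx, by, sy, one_sample=not two_sample)
    else:
        raise KeyError(f"unknown IVW method {method!r}")
    return (lambda est: (est.theta, est.theta_se))(
        mr.ivw(stats_, se_mode="second_order"))


# --------------------------------------------------------------------- #
# replication runner

class SimulationResult:
    """Per-method Monte-Carlo summary plus the per-replication estimates."""

    def __init__(self, metrics: pd.DataFrame, estimates: dict, scenario,
                 truth: float, n_reps: int, seed):
        self.metrics = metrics
        self.estimates = estimates
        self.scenario = scenario
        self.truth = truth
        self.n_reps = n_reps
        self.seed = seed

    def to_dict(self):
        scen = dataclasses.asdict(self.scenario)
        return {
            "scenario": scen,
            "truth": self.truth,
            "n_reps": self.n_reps,
            "seed": self.seed,
            "metrics": self.metrics.to_dict(orient="records"),
            "estimates": {m: {"est": list(map(float, v["est"])),
                              "se": list(map(float, v["se"]))}
                          for m, v in self.estimates.items()},
        }


def summarize_estimates(estimates, ses, truth):
    """MetricsRow arithmetic from per-replication estimates and SEs."""
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    half = 1.96 * se
    cover = float(np.mean((est - half <= truth) & (truth <= est + half)))
    power = float(np.mean(np.abs(est / se) > 1.96))
    return {
        "mean": float(est.mean()),
        "emp_sd": float(est.std(ddof=1)) if est.size > 1 else np.nan,
        "mean_se": float(se.mean()),
        "coverage": cover,
        "power": power,
    }


def run_replications(scenario, methods, n_reps, seed, boot_M=0) -> SimulationResult:
    """Run ``n_reps`` independent replications of a scenario.

    Each replication draws a dataset from an independent child stream of
    ``seed`` and applies every requested estimator; failed fits are logged,
    counted and excluded from the metrics.  ``boot_M`` > 0 activates
    bootstrap SEs for adjusted 2SLS arms.
    """
    scenario = resolve_alpha_R(scenario, seed=seed)
    is_mr = isinstance(scenario, MRScenario)
    if is_mr:
        if scenario.K == 1:
            estimator = _mr_wald_estimate
        elif scenario.design == "one_sample":
            estimator = lambda m, rep, rng=None: _mr_tsls_estimate(
                m, rep, boot_M, rng)
        else:
            estimator = _mr_ivw_estimate
    else:
        estimator = _regression_estimate

    logger.info("scenario=%s methods=%s reps=%d seed=%s", scenario, methods,
                n_reps, seed)
    results = {m: {"est": [], "se": []} for m in methods}
    failures = {m: 0 for m in methods}
    children = np.random.SeedSequence(seed).spawn(n_reps)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        rep = (gen_mr(scenario, rng=rng) if is_mr
               else gen_regression(scenario, rng=rng))
        for m in methods:
            try:
                if is_mr and scenario.K > 1 and scenario.design == "one_sample":
                    est, se = estimator(m, rep, rng=rng)
                else:
                    est, se = estimator(m, rep)
            except (SelectMRError, np.linalg.LinAlgError) as err:
                failures[m] += 1
                logger.warning("rep %d method %s failed: %s", i, m, err)
                continue
            results[m]["est"].append(est)
            results[m]["se"].append(se)

    rows = []
    for m in methods:
        if not results[m]["est"]:
            raise SelectMRError(f"method {m!r}: zero successful replications")
        row = {"method": m}
        row.update(summarize_estimates(results[m]["est"], results[m]["se"],
                                       scenario.truth))
        row["n_failed"] = failures[m]
        rows.append(row)
    metrics = pd.DataFrame(rows, columns=["method", "mean", "emp_sd",
                                          "mean_se", "coverage", "power",
                                          "n_failed"])
    return SimulationResult(metrics, results, scenario, scenario.truth,
                            n_reps, seed)
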