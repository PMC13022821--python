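"""TTW homogeneous-selection-bias model: likelihood evaluation against a
naive oracle, propensity stage, partial and full optimization, GLM
families, and parameter recovery on self-consistent data."""

import numpy as np
import pytest
from scipy import optimize, special
import statsmodels.api as sm

from selectmr import (SelectionDataset, fit_propensity, ttw_fit_full,
                      ttw_fit_glm, ttw_fit_partial, ttw_loglik)
from selectmr.exceptions import IdentificationError
from selectmr.ttw import TTWModel

from conftest import make_ttw_data


def naive_ttw_loglik(params, data):
    """Independent per-observation summation of the TTW likelihood."""
    p = data.n_outcome_params
    beta = params[:p]
    eta = params[p:2 * p]
    alpha = params[2 * p:2 * p + data.n_selection_params]
    sigma2 = params[-1]
    total = 0.0
    for i in range(data.nobs):
        pi_i = 1.0 / (1.0 + np.exp(-(data.selection_design[i] @ alpha)))
        r_i = int(data.selected[i])
        total += np.log(pi_i if r_i else 1.0 - pi_i)
        if r_i:
            mu_i = (data.outcome_design[i] @ beta
                    + (data.outcome_design[i] @ eta) * (1.0 - pi_i))
            total += (-0.5 * np.log(2 * np.pi * sigma2)
                      - 0.5 * (data.outcome[i] - mu_i) ** 2 / sigma2)
    return total


class TestPropensity:
    def test_intercept_only_half_selected_gives_zero(self):
        n = 4000
        r = np.zeros(n, dtype=int)
        r[: n // 2] = 1
        fit = fit_propensity(np.ones((n, 1)), r)
        assert fit.alpha[0] == pytest.approx(0.0, abs=1e-8)

    def test_null_coefficient_recovery(self, rng):
        n = 100_000
        z = rng.standard_normal(n)
        W = np.column_stack([np.ones(n), z])
        r = rng.random(n) < special.expit(0.2 + 0.0 * z)
        fit = fit_propensity(W, r)
        assert abs(fit.alpha[1]) < 4 * np.sqrt(fit.cov[1, 1])

    def test_matches_generic_numeric_maximizer(self, rng):
        n = 2000
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        W = np.column_stack([np.ones(n), x, z])
        r = (rng.random(n) < special.expit(W @ [0.2, 0.5, -0.7])).astype(int)

        def negll(a):
            u = W @ a
            return -np.where(r, special.log_expit(u),
                             special.log_expit(-u)).sum()

        brute = optimize.minimize(negll, np.zeros(3), method="BFGS",
                                  options={"gtol": 1e-12})
        fit = fit_propensity(W, r)
        np.testing.assert_allclose(fit.alpha, brute.x, atol=1e-6)

    def test_fitted_pi_monotone_in_linear_predictor(self, ttw_data):
        fit = fit_propensity(ttw_data.selection_design, ttw_data.selected)
        lin = ttw_data.selection_design @ fit.alpha
        order = np.argsort(lin)
        assert np.all(np.diff(fit.fitted_pi[order]) >= 0)


class TestLikelihood:
    def test_equals_naive_summation(self, rng):
        data = make_ttw_data(50, [1.0, 0.5], [0.8, -0.3], [0.2, 0.5, 0.8],
                             1.0, rng)
        params = np.array([0.9, 0.4, 0.5, -0.2, 0.1, 0.4, 0.7, 1.3])
        assert ttw_loglik(params, data) == pytest.approx(
            naive_ttw_loglik(params, data), abs=1e-10)

    def test_zero_eta_factorizes(self, ttw_data):
        # with eta = 0 the likelihood is (logistic loglik of R) +
        # (Gaussian loglik of Y on X over selected rows)
        d = ttw_data
        beta = np.array([1.0, 0.4])
        alpha = np.array([0.1, 0.4, 0.9])
        sigma2 = 1.21
        params = np.concatenate([beta, [0.0, 0.0], alpha, [sigma2]])
        u = d.selection_design @ alpha
        bern = np.where(d.selected, special.log_expit(u),
                        special.log_expit(-u)).sum()
        resid = d.outcome[d.selected] - d.outcome_design[d.selected] @ beta
        gauss = (-0.5 * np.log(2 * np.pi * sigma2)
                 - 0.5 * resid ** 2 / sigma2).sum()
        assert ttw_loglik(params, d) == pytest.approx(bern + gauss, rel=1e-12)

    def test_saturated_selection_removes_bias_term(self, ttw_data):
        # pi -> 1 for everyone: the outcome mean reduces to X'beta whatever
        # eta is
        d = ttw_data
        alpha = np.array([40.0, 0.0, 0.0])
        base = ttw_loglik(np.array([1.0, 0.5, 0.0, 0.0, *alpha, 1.0]), d)
        with_eta = ttw_loglik(np.array([1.0, 0.5, 5.0, -3.0, *alpha, 1.0]), d)
        assert with_eta == pytest.approx(base, abs=1e-6)

    def test_invariant_to_compensated_rescaling(self, ttw_data):
        d = ttw_data
        fit = ttw_fit_partial(d)
        scale = 5.0
        scaled = SelectionDataset(
            outcome_design=d.outcome_design,
            selection_design=d.selection_design * np.array([1.0, 1.0, scale]),
            outcome=d.outcome, selected=d.selected)
        fit2 = ttw_fit_partial(scaled)
        assert fit.llf == pytest.approx(fit2.llf, abs=1e-6)
        assert fit.alpha_prop[2] == pytest.approx(scale * fit2.alpha_prop[2],
                                                  rel=1e-5)


class TestPartialFit:
    def test_matches_brute_force_stage_two(self, rng):
        # polish a perturbed start with a generic optimizer of the stage-2
        # objective (pi fixed at the fitted propensity) and compare
        data = make_ttw_data(2000, [1.0, 0.5], [0.8, -0.3], [0.2, 0.5, 0.8],
                             1.0, rng)
        fit = ttw_fit_partial(data)
        pi = fit.fitted_pi
        sel = data.selected
        A = np.hstack([data.outcome_design[sel],
                       (1 - pi[sel])[:, None] * data.outcome_design[sel]])
        y = data.outcome[sel]

        def neg(t):
            coefs, logs2 = t[:-1], t[-1]
            s2 = np.exp(logs2)
            resid = y - A @ coefs
            return 0.5 * (len(y) * np.log(2 * np.pi * s2)
                          + resid @ resid / s2)

        t0 = np.concatenate([fit.params, fit.eta, [np.log(fit.sigma2)]]) + 0.05
        brute = optimize.minimize(neg, t0, method="Nelder-Mead",
                                  options={"xatol": 1e-10, "fatol": 1e-12,
                                           "maxiter": 50000})
        np.testing.assert_allclose(
            np.concatenate([fit.params, fit.eta]), brute.x[:-1], atol=1e-4)
        assert fit.sigma2 == pytest.approx(np.exp(brute.x[-1]), abs=1e-4)

    def test_requires_selection_instrument(self, rng):
        # no instrument in the propensity model: pi is constant, the bias
        # column is proportional to X, and (beta, eta) are not separable
        n = 1000
        x = rng.standard_normal(n)
        r = rng.random(n) < 0.5
        y = np.where(r, 1 + 0.5 * x + rng.standard_normal(n), np.nan)
        data = SelectionDataset(
            outcome_design=np.column_stack([np.ones(n), x]),
            selection_design=np.ones((n, 1)),
            outcome=y, selected=r)
        with pytest.raises(IdentificationError):
            ttw_fit_partial(data)

    def test_parameter_recovery_improves_with_n(self):
        errs = []
        for n in (1000, 10_000, 100_000):
            e_beta, e_eta = [], []
            for s in range(3):
                r = np.random.default_rng(2000 + s)
                d = make_ttw_data(n, [1.0, 0.5], [0.8, -0.3],
                                  [0.2, 0.5, 0.8], 1.0, r)
                fit = ttw_fit_partial(d)
                e_beta.append(abs(fit.params[1] - 0.5))
                e_eta.append(abs(fit.eta[1] - (-0.3)))
            errs.append(np.mean(e_beta) + np.mean(e_eta))
        assert errs[2] < errs[0]
        assert errs[2] < 0.05


class TestFullFit:
    def test_full_loglik_dominates_partial(self, ttw_data):
        partial = ttw_fit_partial(ttw_data)
        full = ttw_fit_full(ttw_data)
        assert full.llf >= partial.llf - 1e-8

    def test_gradient_vanishes_at_optimum(self, rng):
        data = make_ttw_data(500, [1.0, 0.5], [0.8, -0.3], [0.2, 0.5, 0.8],
                             1.0, rng)
        fit = ttw_fit_full(data)
        packed = np.concatenate([fit.params, fit.eta, fit.alpha_prop,
                                 [fit.sigma2]])
        grad = optimize.approx_fprime(
            packed, lambda p: ttw_loglik(p, data) / data.nobs, 1e-7)
        assert np.linalg.norm(grad, np.inf) < 1e-4

    def test_agrees_with_partial_on_well_specified_data(self, ttw_data):
        partial = ttw_fit_partial(ttw_data)
        full = ttw_fit_full(ttw_data)
        np.testing.assert_allclose(full.params, partial.params, atol=0.05)


class TestGLMFamilies:
    @pytest.mark.parametrize("family", ["logistic", "poisson"])
    def test_zero_eta_data_reduces_to_plain_glm(self, family, rng):
        # when no selection bias is simulated, the bias coefficients are
        # near zero and beta matches the ordinary GLM closely
        n = 20_000
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        lin = 0.5 + 0.3 * x
        mu = special.expit(lin) if family == "logistic" else np.exp(lin)
        y = (rng.binomial(1, mu) if family == "logistic"
             else rng.poisson(mu)).astype(float)
        r = rng.random(n) < special.expit(0.2 + 0.7 * z)   # MCAR given z
        data = SelectionDataset(
            outcome_design=np.column_stack([np.ones(n), x]),
            selection_design=np.column_stack([np.ones(n), x, z]),
            outcome=np.where(r, y, np.nan), selected=r)
        fit = ttw_fit_glm(data, family=family)
        fam = (sm.families.Binomial() if family == "logistic"
               else sm.families.Poisson())
        glm = sm.GLM(y[r], data.outcome_design[r], family=fam).fit()
        assert fit.params[1] == pytest.approx(glm.params[1],
                                              abs=3 * glm.bse[1])

    def test_poisson_matches_brute_force_maximizer(self, rng):
        n = 2000
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        W = np.column_stack([np.ones(n), x, z])
        pi = special.expit(W @ [0.3, 0.4, 0.8])
        r = rng.random(n) < pi
        eta_lin = 0.5 - 0.2 * x
        mu = np.exp(1.0 + 0.1 * x + eta_lin * (1 - pi))
        y = np.where(r, rng.poisson(mu).astype(float), np.nan)
        data = SelectionDataset(
            outcome_design=np.column_stack([np.ones(n), x]),
            selection_design=W, outcome=y, selected=r)
        fit = ttw_fit_glm(data, family="poisson")
        pi_hat = fit.fitted_pi[r]
        A = np.hstack([data.outcome_design[r],
                       (1 - pi_hat)[:, None] * data.outcome_design[r]])
        yy = y[r]

        def neg(c):
            lam = np.exp(A @ c)
            return float(np.sum(lam - yy * (A @ c)))

        t0 = np.concatenate([fit.params, fit.eta]) + 0.02
        brute = optimize.minimize(neg, t0, method="BFGS",
                                  options={"gtol": 1e-12})
        np.testing.assert_allclose(np.concatenate([fit.params, fit.eta]),
                                   brute.x, atol=1e-4)
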