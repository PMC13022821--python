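"""Heckman sample-selection model: Mills ratio identities, probit first
stage, two-step and ML estimation, and the bivariate-probit binary variant."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, optimize, special, stats

import selectmr
from selectmr import (SelectionDataset, fit_probit, heckman_binary_ml,
                      heckman_ml, heckman_two_step, inverse_mills)
from selectmr.exceptions import SeparationError
from selectmr.heckman import HeckmanSelectionModel, bivariate_normal_cdf

from conftest import make_probit_selection_data


# ---------------------------------------------------------------- Mills ratio

class TestInverseMills:
    def test_value_at_zero(self):
        # phi(0) / (1 - Phi(0)) = 2 phi(0)
        assert inverse_mills(0.0) == pytest.approx(2 * stats.norm.pdf(0.0),
                                                   abs=1e-12)

    def test_against_quadrature_oracle(self):
        # independent evaluation of phi(v)/(1-Phi(v)) by integrating the
        # normal tail numerically
        for v in (-3.0, -1.0, 0.5, 1.0, 2.5):
            tail, _ = integrate.quad(stats.norm.pdf, v, np.inf)
            assert inverse_mills(v) == pytest.approx(
                stats.norm.pdf(v) / tail, abs=1e-10)

    def test_asymptotics(self):
        # lambda -> 0 on the far left; lambda / v -> 1 on the far right
        assert inverse_mills(-30.0) < 1e-100
        assert inverse_mills(35.0) / 35.0 == pytest.approx(1.0, rel=1e-3)

    def test_finite_and_stable_over_wide_range(self):
        v = np.linspace(-40, 40, 4001)
        lam = inverse_mills(v)
        assert np.all(np.isfinite(lam))

    @given(st.floats(min_value=-35, max_value=35))
    @settings(deadline=None, max_examples=60)
    def test_exceeds_max_of_zero_and_argument(self, v):
        # the normal hazard dominates both 0 and its argument
        assert inverse_mills(v) > max(0.0, v)

    def test_strictly_increasing(self):
        v = np.linspace(-38, 38, 2000)
        assert np.all(np.diff(inverse_mills(v)) > 0)


# ------------------------------------------------------------------- probit

class TestProbitFirstStage:
    def test_intercept_only_closed_form(self, rng):
        # MLE of an intercept-only probit is Phi^{-1}(selected fraction)
        n = 5000
        r = np.zeros(n, dtype=int)
        r[:3000] = 1
        fit = fit_probit(np.ones((n, 1)), r)
        assert fit.params[0] == pytest.approx(stats.norm.ppf(0.6), abs=1e-6)

    def test_null_coefficient_recovery(self, rng):
        n = 100_000
        z = rng.standard_normal(n)
        W = np.column_stack([np.ones(n), z])
        r = rng.random(n) < special.ndtr(0.3 + 0.0 * z)
        fit = fit_probit(W, r)
        se = np.sqrt(fit.cov[1, 1])
        assert abs(fit.params[1]) < 4 * se

    def test_matches_generic_numeric_maximizer(self, rng):
        n = 2000
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        W = np.column_stack([np.ones(n), x, z])
        r = (rng.random(n) < special.ndtr(W @ [0.2, 0.5, -0.7])).astype(int)

        def negll(g):
            u = W @ g
            return -(np.where(r, special.log_ndtr(u),
                              special.log_ndtr(-u))).sum()

        brute = optimize.minimize(negll, np.zeros(3), method="BFGS",
                                  options={"gtol": 1e-12})
        fit = fit_probit(W, r)
        np.testing.assert_allclose(fit.params, brute.x, atol=1e-6)

    def test_separation_raises(self):
        x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
        r = (x > 0).astype(int)
        with pytest.raises(SeparationError):
            fit_probit(np.column_stack([np.ones(6), x]), r)


# --------------------------------------------------------- two-step estimator

class TestTwoStep:
    def test_constant_mills_ratio_reduces_to_cca_slopes(self, rng):
        # intercept-only selection design: lambda-hat is constant and is
        # absorbed by the intercept, so slopes equal complete-case OLS
        n = 1000
        x = rng.standard_normal(n)
        y = 1.0 + 0.5 * x + rng.standard_normal(n)
        r = rng.random(n) < 0.6
        data = SelectionDataset(
            outcome_design=np.column_stack([np.ones(n), x]),
            selection_design=np.ones((n, 1)),
            outcome=np.where(r, y, np.nan), selected=r)
        with pytest.warns(UserWarning):
            fit = heckman_two_step(data)
        import statsmodels.api as sm
        ols = sm.OLS(y[r], np.column_stack([np.ones(r.sum()), x[r]])).fit()
        assert fit.params[1] == pytest.approx(ols.params[1], abs=1e-10)

    def test_agrees_with_joint_ml(self, rng):
        data = make_probit_selection_data(
            n=500, beta=[1.0, 0.5], gamma=[0.3, 0.4, 0.7],
            sigma1=1.2, rho=0.5, rng=rng)
        ts = heckman_two_step(data)
        ml = heckman_ml(data)
        assert abs(ts.params[1] - ml.params[1]) < 2 * ts.bse[1]

    def test_independent_selection_gives_zero_rho_and_ols(self, rng):
        # sigma12 = 0: outcome independent of selection; rho_sigma -> 0 and
        # beta matches full-data OLS within Monte-Carlo error
        data = make_probit_selection_data(
            n=50_000, beta=[1.0, 0.5], gamma=[0.0, 0.3, 0.6],
            sigma1=1.0, rho=0.0, rng=rng)
        fit = heckman_two_step(data)
        assert abs(fit.rho_sigma) < 3 * fit.rho_sigma_se
        assert fit.params[1] == pytest.approx(0.5, abs=0.02)

    def test_all_selected_falls_back_to_ols(self, rng):
        n = 400
        x = rng.standard_normal(n)
        y = 1 + 0.5 * x + rng.standard_normal(n)
        data = SelectionDataset(
            outcome_design=np.column_stack([np.ones(n), x]),
            selection_design=np.column_stack([np.ones(n), x,
                                              rng.standard_normal(n)]),
            outcome=y, selected=np.ones(n, dtype=bool))
        with pytest.warns(UserWarning):
            fit = heckman_two_step(data)
        assert fit.rho_sigma == 0.0

    def test_diagnostic_plain_ols_se_mode(self, probit_data):
        corrected = heckman_two_step(probit_data)
        plain = heckman_two_step(probit_data, ols_se=True)
        np.testing.assert_allclose(corrected.params, plain.params)
        assert not np.allclose(corrected.bse, plain.bse)


# ----------------------------------------------------------- maximum likelihood

class TestMaximumLikelihood:
    def test_loglik_dominates_two_step_and_random_grid(self, rng):
        data = make_probit_selection_data(
            n=300, beta=[1.0, 0.5], gamma=[0.3, 0.4, 0.7],
            sigma1=1.2, rho=0.5, rng=rng)
        model = HeckmanSelectionModel(data)
        ml = model.fit(method="ml")
        ts = model.fit(method="two-step")
        ts_packed = model._pack(ts.params, ts.gamma, ts.sigma1,
                                np.clip(ts.rho, -0.99, 0.99))
        assert ml.llf >= model.loglike(ts_packed) - 1e-8
        center = model._pack(ml.params, ml.gamma, ml.sigma1,
                             np.clip(ml.rho, -0.99, 0.99))
        for _ in range(1000):
            trial = center + rng.normal(scale=0.3, size=center.size)
            assert model.loglike(trial) <= ml.llf + 1e-8

    def test_loglik_invariant_to_rescaling_selection_column(self, probit_data):
        ml1 = heckman_ml(probit_data)
        scaled = SelectionDataset(
            outcome_design=probit_data.outcome_design,
            selection_design=probit_data.selection_design * np.array([1, 1, 10.0]),
            outcome=probit_data.outcome, selected=probit_data.selected)
        ml2 = heckman_ml(scaled)
        assert ml1.llf == pytest.approx(ml2.llf, abs=1e-6)
        assert ml1.gamma[2] == pytest.approx(10 * ml2.gamma[2], rel=1e-4)

    def test_parameter_recovery_improves_with_n(self):
        # self-consistent data: bias of the ML slope shrinks with n
        errs = []
        for n in (1000, 100_000):
            e = []
            for s in range(3):
                r = np.random.default_rng(1000 + s)
                d = make_probit_selection_data(
                    n=n, beta=[1.0, 0.5], gamma=[0.3, 0.4, 0.7],
                    sigma1=1.2, rho=0.5, rng=r)
                e.append(abs(heckman_ml(d).params[1] - 0.5))
            errs.append(np.mean(e))
        assert errs[-1] < errs[0]
        assert errs[-1] < 0.02


# ------------------------------------------------------------ binary outcome

class TestBivariateProbit:
    def test_bvn_cdf_against_numerical_integration(self):
        for h, k, rho in [(0.5, -0.3, 0.6), (1.2, 0.8, -0.4), (0.0, 0.7, 0.3)]:
            oracle = stats.multivariate_normal(
                mean=[0, 0], cov=[[1, rho], [rho, 1]]).cdf([h, k])
            assert bivariate_normal_cdf(h, k, rho) == pytest.approx(
                oracle, abs=1e-10)

    def test_zero_correlation_matches_separate_probits(self, rng):
        n = 8000
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        ystar = 0.3 + 0.5 * x + rng.standard_normal(n)
        r = 0.2 + 0.4 * x + 0.7 * z + rng.standard_normal(n) > 0
        data = SelectionDataset(
            outcome_design=np.column_stack([np.ones(n), x]),
            selection_design=np.column_stack([np.ones(n), x, z]),
            outcome=np.where(r, (ystar > 0).astype(float), np.nan),
            selected=r)
        fit = heckman_binary_ml(data)
        import statsmodels.api as sm
        sep = sm.Probit((ystar[r] > 0).astype(int),
                        data.outcome_design[r]).fit(disp=0)
        assert abs(fit.rho) < 0.12
        np.testing.assert_allclose(fit.params, sep.params, atol=0.08)

    def test_matches_generic_numeric_maximizer(self, rng):
        n = 2000
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        e2 = rng.standard_normal(n)
        e1 = 0.5 * e2 + np.sqrt(1 - 0.25) * rng.standard_normal(n)
        r = 0.2 + 0.3 * x + 0.6 * z + e2 > 0
        ybin = (0.3 + 0.5 * x + e1 > 0).astype(float)
        data = SelectionDataset(
            outcome_design=np.column_stack([np.ones(n), x]),
            selection_design=np.column_stack([np.ones(n), x, z]),
            outcome=np.where(r, ybin, np.nan), selected=r)
        model = HeckmanSelectionModel(data)
        fit = model.fit(method="binary-ml")
        brute = optimize.minimize(
            lambda p: -model._binary_loglike(p),
            np.concatenate([fit.params, fit.gamma, [np.arctanh(fit.rho)]])
            + 0.05,
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 20000})
        packed = np.concatenate([fit.params, fit.gamma,
                                 [np.arctanh(fit.rho)]])
        np.testing.assert_allclose(packed, brute.x, atol=1e-5)


def test_summary_and_json_roundtrip(probit_data, tmp_path):
    from selectmr.io import write_fit_json
    import json
    fit = heckman_two_step(probit_data)
    text = fit.summary()
    assert "Outcome equation" in text and "probit" in text
    write_fit_json(fit, tmp_path / "fit.json")
    loaded = json.loads((tmp_path / "fit.json").read_text())
    np.testing.assert_allclose(loaded["beta"], fit.params)
    assert loaded["method"] == "two-step"
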