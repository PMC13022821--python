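"""Shared fixtures: self-consistent generators for the two selection models.

The simulation module generates data with *logistic* selection (the study
conditions); the fixtures here instead generate data from each model's own
assumptions (bivariate-normal/probit for Heckman, logistic propensity with
a homogeneous additive bias for TTW), which is what parameter-recovery and
oracle tests need.
"""

import numpy as np
import pytest
from scipy import special

from selectmr.data import SelectionDataset


def make_probit_selection_data(n, beta, gamma, sigma1, rho, rng):
    """Data from the bivariate-normal sample-selection model itself.

    Outcome Y = [1, x] beta + e1 observed iff [1, x, z] gamma + e2 > 0,
    with corr(e1, e2) = rho and sd(e1) = sigma1, sd(e2) = 1.
    """
    beta = np.asarray(beta, float)
    gamma = np.asarray(gamma, float)
    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    e2 = rng.standard_normal(n)
    e1 = sigma1 * (rho * e2 + np.sqrt(1 - rho ** 2) * rng.standard_normal(n))
    X = np.column_stack([np.ones(n), x])
    W = np.column_stack([np.ones(n), x, z])
    r = W @ gamma + e2 > 0
    y = np.where(r, X @ beta + e1, np.nan)
    return SelectionDataset(outcome_design=X, selection_design=W,
                            outcome=y, selected=r)


def make_ttw_data(n, beta, eta, alpha, sigma, rng):
    """Data from the homogeneous-selection-bias model itself.

    Logistic propensity pi = expit([1, x, z] alpha); selected outcomes are
    drawn from N([1,x] beta + ([1,x] eta)(1 - pi), sigma^2).
    """
    beta = np.asarray(beta, float)
    eta = np.asarray(eta, float)
    alpha = np.asarray(alpha, float)
    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    X = np.column_stack([np.ones(n), x])
    W = np.column_stack([np.ones(n), x, z])
    pi = special.expit(W @ alpha)
    r = rng.random(n) < pi
    mean = X @ beta + (X @ eta) * (1.0 - pi)
    y = np.where(r, mean + sigma * rng.standard_normal(n), np.nan)
    return SelectionDataset(outcome_design=X, selection_design=W,
                            outcome=y, selected=r)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def probit_data(rng):
    """Moderate-size dataset from the Heckman model's own assumptions."""
    return make_probit_selection_data(
        n=2000, beta=[1.0, 0.5], gamma=[0.3, 0.4, 0.7],
        sigma1=1.2, rho=0.5, rng=rng)


@pytest.fixture
def ttw_data(rng):
    """Moderate-size dataset from the TTW model's own assumptions."""
    return make_ttw_data(
        n=2000, beta=[1.0, 0.5], eta=[0.8, -0.3],
        alpha=[0.2, 0.5, 0.8], sigma=1.0, rng=rng)
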