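import numpy as np
import pytest

import colonssm as cs


@pytest.fixture(scope="session")
def default_params():
    return cs.make_default_params()


@pytest.fixture(scope="session")
def homogeneous_params(default_params):
    """Published rates with the growth-limiting decay switched off, so the
    closed-form expected numbers apply."""
    return default_params.with_updates(delta1=0.0, delta2=0.0)


@pytest.fixture(scope="session")
def seer_table():
    return cs.load_seer_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


def draw_box_params(rng, delta_zero=True):
    """One random parameter set log-uniform inside the default prior box."""
    from colonssm.fit import THETA_NAMES, default_prior, params_from_theta

    prior = default_prior()
    theta = {}
    for name in THETA_NAMES:
        lo, hi = prior.bounds[name]
        theta[name] = 10.0 ** rng.uniform(np.log10(lo) + 0.05, np.log10(hi) - 0.05)
    if delta_zero:
        theta["delta1"] = 0.0
        theta["delta2"] = 0.0
    params = params_from_theta(theta)
    if delta_zero:
        params = params.with_updates(delta1=0.0, delta2=0.0)
    return params


def discrete_expectation(params, t_units, dt=1.0):
    """Exact mean of the discrete-time stochastic system: the one-step
    linear recursion of the conditional expectations (independent oracle,
    coded apart from the package's integrators)."""
    n_steps = int(round(t_units / dt))
    uI = np.zeros(params.k1 - 1)
    uJ = np.zeros(params.k2 - 1)
    for s in range(n_steps):
        t = s * dt
        gI = params.birth_rates_I(t) - params.d_I
        gJ = params.birth_rates_J(t) - params.d_J
        dI = gI * uI
        dI[0] += params.lambda_I
        dI[1:] += params.alpha[:-1] * uI[:-1]
        dJ = gJ * uJ
        dJ[0] += params.lambda_J
        dJ[1:] += params.beta[:-1] * uJ[:-1]
        uI = uI + dt * dI
        uJ = uJ + dt * dJ
    return uI, uJ


@pytest.fixture(scope="session")
def small_fit(seer_table):
    """One tiny but complete multi-level Gibbs fit, shared across tests."""
    cfg = cs.GibbsConfig(K=20, n_iter=8, burn_in=3, chains=2, de_maxiter=40,
                         de_popsize=10, de_starts=1, n_scale=0.01)
    return cs.gibbs_fit(seer_table, config=cfg, seed=7)
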