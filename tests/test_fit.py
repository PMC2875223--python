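"""Prior, data augmentation, conditional updates and the Gibbs driver."""

import numpy as np
import pytest
from scipy.stats import chisquare

import colonssm as cs
from colonssm.fit import (
    THETA_NAMES,
    augment_latents,
    conditional_update_theta1,
    conditional_update_theta2,
    default_prior,
    params_from_theta,
    theta_from_params,
    weighted_resample,
)
from colonssm.incidence import IncidenceTable


class TestLogPrior:
    def test_published_estimates_inside_box(self, default_params):
        assert cs.log_prior(default_params) == 0.0

    def test_excess_mutation_rate_outside(self, default_params):
        p = default_params.with_updates(
            alpha=np.array([1.0e-3, 3.2e-3, 1.2e-6]))
        assert cs.log_prior(p) == -np.inf

    def test_boundary_counts_as_outside(self):
        prior = default_prior()
        theta = theta_from_params(cs.make_default_params())
        theta["alpha1"] = prior.bounds["alpha1"][0]  # exactly the bound
        assert cs.log_prior(theta, prior) == -np.inf


class TestWeightedResample:
    def test_uniform_weights_indistinguishable_from_uniform(self, rng):
        idx, w = weighted_resample(np.zeros(10), 10000, rng)
        np.testing.assert_allclose(w, 0.1)
        observed = np.bincount(idx, minlength=10)
        assert chisquare(observed).pvalue > 0.01

    def test_two_candidate_frequencies(self, rng):
        n = 10000
        idx, _ = weighted_resample(np.log([0.9, 0.1]), n, rng)
        freq = (idx == 0).mean()
        se = np.sqrt(0.9 * 0.1 / n)
        assert abs(freq - 0.9) < 3 * se

    def test_single_candidate(self, rng):
        idx, w = weighted_resample(np.array([-5.0]), 1, rng)
        assert idx[0] == 0 and w[0] == 1.0

    def test_all_zero_weights_error(self, rng):
        with pytest.raises(RuntimeError, match="weights"):
            weighted_resample(np.full(4, -np.inf), 1, rng)


class TestAugmentLatents:
    def test_k1_returns_single_candidate(self, default_params, seer_table, rng):
        lat = augment_latents(default_params, seer_table, 1, rng,
                              cohort_size=1e4)
        assert lat.K == 1 and lat.selected[0] == 0
        assert lat.weights[0] == pytest.approx(1.0)

    def test_accounting_identity_on_sufficient_statistics(self, default_params,
                                                          rng):
        # total inflow minus outflow must equal the final polyp-stage count
        from colonssm.fit import _simulate_paths_batch

        lat = _simulate_paths_batch(default_params, 5, 100, rng)
        net = (lat.M_I[:, 0]             # inflow I1 -> I2 mutations
               + lat.B_I2.sum(axis=1) - lat.D_I2.sum(axis=1))
        np.testing.assert_array_equal(net, lat.I2[:, -1])

    def test_ess_reported(self, default_params, seer_table, rng):
        lat = augment_latents(default_params, seer_table, 8, rng,
                              cohort_size=1e4)
        assert 1.0 <= lat.ess <= 8.0


def _latents_stub(**overrides):
    """Minimal LatentPaths with prescribed sufficient statistics."""
    from colonssm.fit import LatentPaths

    m = 4
    base = dict(
        K=1, dt=1.0, cohort_size=1.0, t=np.arange(m + 1, dtype=float),
        I2=np.zeros((1, m + 1), dtype=int), I3=np.zeros((1, m + 1), dtype=int),
        J3=np.zeros((1, m + 1), dtype=int), J4=np.zeros((1, m + 1), dtype=int),
        B_I2=np.zeros((1, m), dtype=int), D_I2=np.zeros((1, m), dtype=int),
        B_J3=np.zeros((1, m), dtype=int), D_J3=np.zeros((1, m), dtype=int),
        M0_I=np.array([0]), M0_J=np.array([0]),
        M_I=np.zeros((1, 3), dtype=int), M_J=np.zeros((1, 4), dtype=int),
        exp_I=np.zeros((1, 3)), exp_J=np.zeros((1, 4)),
        B_I3=np.array([0]), D_I3=np.array([0]),
        B_J4=np.array([0]), D_J4=np.array([0]),
        log_weights=np.zeros(1), weights=np.ones(1),
        selected=np.array([0]),
    )
    base.update(overrides)
    return LatentPaths(**base)


class TestConditionalUpdateTheta1:
    def test_poisson_mode_matches_grid_search_oracle(self, default_params):
        # 100 mutation events over 1e6 cell-units of exposure
        prior = default_prior()
        lat = _latents_stub(M_I=np.array([[100, 0, 0]]),
                            exp_I=np.array([[1.0e6, 0.0, 0.0]]))
        new = conditional_update_theta1(lat, prior, default_params)
        # independent 1-D grid maximization of the conditional log density
        grid = np.linspace(np.log(1e-6), np.log(1e-3), 40001)
        logdens = 100 * grid - 1.0e6 * np.exp(grid)
        oracle = np.exp(grid[np.argmax(logdens)])
        assert new.alpha[0] == pytest.approx(oracle, rel=1e-3)
        assert new.alpha[0] == pytest.approx(1.0e-4, rel=1e-3)

    def test_zero_events_projects_to_lower_bound(self, default_params):
        prior = default_prior()
        lat = _latents_stub(M_I=np.array([[0, 0, 0]]),
                            exp_I=np.array([[1.0e6, 0.0, 0.0]]))
        new = conditional_update_theta1(lat, prior, default_params)
        lo, hi = prior.bounds["alpha1"]
        assert lo < new.alpha[0] < lo + 1e-4 * (hi - lo)

    def test_zero_exposure_skips_update(self, default_params):
        prior = default_prior()
        lat = _latents_stub()
        new = conditional_update_theta1(lat, prior, default_params)
        assert new.beta[0] == default_params.beta[0]

    def test_multinomial_mle_for_last_stage(self, default_params):
        # birth count 190, death count 30 over 1e4 cell-units: the mode is
        # (b, d) = (1.9e-2, 3e-3), net proliferation interior to its box
        prior = default_prior()
        lat = _latents_stub(B_I3=np.array([190]), D_I3=np.array([30]),
                            exp_I=np.array([[0.0, 0.0, 1.0e4]]))
        new = conditional_update_theta1(lat, prior, default_params)
        assert new.gamma_I[2] == pytest.approx(1.6e-2, rel=1e-9)
        assert new.b_I[2] == pytest.approx(1.9e-2, rel=1e-9)
        assert new.d_I[2] == pytest.approx(3.0e-3, rel=1e-9)


class TestConditionalUpdateTheta2:
    def _latents_with_paths(self, params, table, rng, K=6):
        return augment_latents(params, table, K, rng, cohort_size=1e4)

    def test_zero_cases_mode_at_lower_corner(self, default_params, rng):
        table = IncidenceTable(np.array([40.0, 60.0]), np.array([60.0, 80.0]),
                               np.array([10000, 10000]), np.array([0, 0]))
        prior = default_prior()
        lat = self._latents_with_paths(default_params, table, rng)
        new = conditional_update_theta2(default_params, table, lat, prior)
        lo_a, hi_a = prior.bounds["alpha3"]
        lo_b, hi_b = prior.bounds["beta4"]
        assert new.alpha[-1] < lo_a + 1e-3 * (hi_a - lo_a)
        assert new.beta[-1] < lo_b + 1e-3 * (hi_b - lo_b)

    def test_self_consistency_recovers_known_rates(self, default_params,
                                                   seer_table, rng):
        # synthetic y at known (alpha3, beta4) given the same latent paths
        prior = default_prior()
        lat = self._latents_with_paths(default_params, seer_table, rng, K=3)
        from colonssm.fit import _path_tau

        true = default_params
        tau = _path_tau(lat, true, seer_table)[lat.selected[0]]
        table = IncidenceTable(seer_table.age_lo, seer_table.age_hi,
                               seer_table.n,
                               np.minimum(rng.poisson(tau), seer_table.n))
        start = true.with_updates(
            alpha=np.array([2.2e-4, 3.2e-3, 5e-6]),
            beta=np.array([3.5e-4, 1.4e-3, 9.3e-3, 2e-6]))
        new = conditional_update_theta2(start, table, lat, prior)
        assert new.alpha[-1] == pytest.approx(true.alpha[-1], rel=0.10)
        assert new.beta[-1] == pytest.approx(true.beta[-1], rel=0.10)

    def test_profile_unimodal_along_alpha3(self, default_params, seer_table,
                                           rng):
        from colonssm.fit import _path_tau

        lat = self._latents_with_paths(default_params, seer_table, rng, K=2)
        tau0 = _path_tau(lat, default_params, seer_table)[lat.selected[0]]
        y = np.minimum(np.round(tau0).astype(int), seer_table.n)
        grid = np.logspace(-8, -4, 60)
        lls = []
        cI, cJ = lat.cum_last_stage()
        for a3 in grid:
            p = default_params.with_updates(
                alpha=np.array([2.2e-4, 3.2e-3, a3]))
            tau = _path_tau(lat, p, seer_table)[lat.selected[0]]
            lls.append(cs.poisson_loglik(y, np.maximum(tau, 1e-300)))
        lls = np.array(lls)
        peak = np.argmax(lls)
        assert np.all(np.diff(lls[:peak + 1]) >= -1e-6)
        assert np.all(np.diff(lls[peak:]) <= 1e-6)


class TestIdentifiability:
    def test_common_shift_of_last_stage_birth_death_leaves_tau(self,
                                                               default_params,
                                                               seer_table):
        tau0 = cs.expected_cases(default_params, seer_table)
        c = 5.0e-3
        shifted = default_params.with_updates(
            b_I=default_params.b_I + np.array([0, 0, c]),
            d_I=default_params.d_I + np.array([0, 0, c]),
            b_J=default_params.b_J + np.array([0, 0, 0, c]),
            d_J=default_params.d_J + np.array([0, 0, 0, c]))
        tau1 = cs.expected_cases(shifted, seer_table)
        mask = tau0 > 1e-12
        assert np.max(np.abs(tau1[mask] / tau0[mask] - 1.0)) < 1e-10


class TestGibbsFit:
    def test_reproducible_given_seed(self, seer_table):
        cfg = cs.GibbsConfig(K=10, n_iter=4, burn_in=1, chains=1,
                             de_maxiter=15, de_popsize=8, de_starts=1,
                             n_scale=0.01)
        a = cs.gibbs_fit(seer_table, config=cfg, seed=3)
        b = cs.gibbs_fit(seer_table, config=cfg, seed=3)
        assert a.dev == b.dev
        assert a.draws.equals(b.draws)
        np.testing.assert_array_equal(a.tau, b.tau)

    def test_draws_respect_prior_box(self, small_fit):
        prior = default_prior()
        kept = small_fit.draws
        for name in THETA_NAMES:
            lo, hi = prior.bounds[name]
            assert np.all(kept[name] > lo) and np.all(kept[name] < hi)

    def test_summary_and_criteria_shape(self, small_fit, seer_table):
        assert set(small_fit.summary.index) == set(THETA_NAMES)
        assert small_fit.p == 15
        assert small_fit.n_points == 18
        assert small_fit.aic == pytest.approx(small_fit.dev + 2 * 15)
        assert small_fit.bic == pytest.approx(
            small_fit.dev + 15 * np.log(18))
        assert len(small_fit.tau) == len(seer_table)

    def test_predictions_consistent_with_expected_cases(self, small_fit,
                                                        seer_table):
        pred = cs.predict_incidence(small_fit, seer_table, force=True)
        risk = cs.age_group_probabilities(small_fit.params, seer_table)
        manual = seer_table.n * small_fit.config.n_scale * risk.QT
        np.testing.assert_allclose(pred["predicted"].to_numpy(), manual,
                                   rtol=1e-10)

    def test_zero_intensity_predicts_zero(self, small_fit, seer_table):
        params0 = small_fit.params.with_updates(lambda_I=0.0, lambda_J=0.0)
        tau = cs.expected_cases(params0, seer_table)
        np.testing.assert_allclose(tau, 0.0)


class TestThetaRoundTrip:
    def test_params_theta_params(self, default_params):
        theta = theta_from_params(default_params)
        rebuilt = params_from_theta(theta, default_params)
        np.testing.assert_allclose(rebuilt.alpha, default_params.alpha)
        np.testing.assert_allclose(rebuilt.gamma_I, default_params.gamma_I)
        np.testing.assert_allclose(rebuilt.gamma_J, default_params.gamma_J)
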