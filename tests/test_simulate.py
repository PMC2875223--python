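"""Stochastic simulator: transition laws, conservation, reproducibility."""

import numpy as np
import pytest

import colonssm as cs
from colonssm.model import PopulationState


class TestSimulateStep:
    def test_zero_state_only_initiations(self, default_params, rng):
        state = PopulationState.zero(default_params)
        new, counts = cs.simulate_step(state, default_params, 1.0, rng)
        assert np.all(counts.B_I == 0) and np.all(counts.D_I == 0)
        assert np.all(counts.M_I == 0) and np.all(counts.M_J == 0)
        assert new.I[0] == counts.M0_I
        assert new.J[0] == counts.M0_J
        assert np.all(new.I[1:] == 0) and np.all(new.J[1:] == 0)

    def test_conservation_identity_exact(self, default_params, rng):
        state = PopulationState(t=0.0, I=np.array([500, 200, 50]),
                                J=np.array([400, 100, 30, 10]))
        for _ in range(50):
            new, c = cs.simulate_step(state, default_params, 1.0, rng)
            expect_I = state.I + c.B_I - c.D_I
            expect_I[0] += c.M0_I
            expect_I[1:] += c.M_I[:-1]
            np.testing.assert_array_equal(new.I, expect_I)
            expect_J = state.J + c.B_J - c.D_J
            expect_J[0] += c.M0_J
            expect_J[1:] += c.M_J[:-1]
            np.testing.assert_array_equal(new.J, expect_J)
            assert np.all(new.I >= 0) and np.all(new.J >= 0)
            state = new

    def test_binomial_moments_of_births_and_deaths(self, default_params):
        # I2 = 1000 cells, b = 7.4e-3, d = 3.8e-3 per unit
        rng = np.random.default_rng(42)
        p = default_params.with_updates(delta1=0.0)
        state = PopulationState(t=0.0, I=np.array([0, 1000, 0]),
                                J=np.zeros(4, dtype=int))
        n_rep = 20000
        B = np.empty(n_rep)
        D = np.empty(n_rep)
        for i in range(n_rep):
            _, c = cs.simulate_step(state, p, 1.0, rng)
            B[i], D[i] = c.B_I[1], c.D_I[1]
        for draw, prob in ((B, 7.4e-3), (D, 3.8e-3)):
            mean_expect = 1000 * prob
            se = np.sqrt(1000 * prob * (1 - prob) / n_rep)
            assert abs(draw.mean() - mean_expect) < 3 * se

    def test_rate_dt_validity_error_names_stage(self, default_params):
        bad = default_params.with_updates(
            b_J=np.array([0.0, 0.0, 0.3, 0.3]),
            d_J=np.array([0.0, 0.0, 0.3, 0.2]))
        state = PopulationState(t=0.0, I=np.zeros(3, dtype=int),
                                J=np.array([0, 0, 5, 0]))
        with pytest.raises(ValueError, match="J_3"):
            cs.simulate_step(state, bad, 2.0, np.random.default_rng(0))


class TestTrajectory:
    def test_zero_intensity_gives_zero_trajectory(self, default_params):
        p = default_params.with_updates(lambda_I=0.0, lambda_J=0.0)
        traj = cs.simulate_trajectory(p, 0.0, 40.0, seed=1)
        assert np.all(traj.I == 0) and np.all(traj.J == 0)

    def test_reproducible_given_seed(self, default_params):
        a = cs.simulate_trajectory(default_params, 0.0, 60.0, seed=123)
        b = cs.simulate_trajectory(default_params, 0.0, 60.0, seed=123)
        np.testing.assert_array_equal(a.I, b.I)
        np.testing.assert_array_equal(a.J, b.J)
        for ca, cb in zip(a.counts, b.counts):
            np.testing.assert_array_equal(ca.M_I, cb.M_I)

    def test_mean_matches_discrete_law_expectation(self, default_params):
        # The exact mean of the unit-step stochastic system follows the
        # linear one-step recursion of the conditional means; the continuum
        # expected-number ODE is its dt -> 0 limit.
        from colonssm.fit import _simulate_paths_batch

        from conftest import discrete_expectation

        t_probe = 120
        rng = np.random.default_rng(7)
        lat = _simulate_paths_batch(default_params, 3000, t_probe, rng)
        uI, uJ = discrete_expectation(default_params, t_probe, dt=1.0)
        for mc, expect in ((lat.I3[:, -1], uI[-1]), (lat.J4[:, -1], uJ[-1])):
            se = mc.std(ddof=1) / np.sqrt(len(mc))
            assert abs(mc.mean() - expect) < 3 * se + 1e-9

    def test_discrete_expectation_converges_to_ode(self, default_params):
        from conftest import discrete_expectation

        series = cs.expected_numbers_ode(default_params, np.array([120.0]))
        err = []
        for dt in (1.0, 0.5, 0.25):
            uI, _ = discrete_expectation(default_params, 120, dt=dt)
            err.append(abs(uI[-1] - series.uI[0, -1]))
        assert err[2] < err[1] < err[0]
        assert err[2] / err[0] < 0.35  # first-order shrinkage

    def test_tidy_export_shape(self, default_params):
        traj = cs.simulate_trajectory(default_params, 0.0, 5.0, seed=3)
        df = traj.to_tidy_frame()
        assert set(df.columns) == {"replicate", "t", "variable", "count"}
        assert len(df) == 6 * 7  # 6 time points x 7 state variables


class TestTumorOnset:
    def test_zero_transformation_rates_no_tumors(self, default_params):
        p = default_params.with_updates(
            alpha=np.array([2.2e-4, 3.2e-3, 0.0]),
            beta=np.array([3.5e-4, 1.4e-3, 9.3e-3, 0.0]))
        traj = cs.simulate_trajectory(p, 0.0, 80.0, seed=5)
        onset = cs.simulate_tumor_onset(traj, p, seed=6)
        assert onset.T1[-1] == 0 and onset.T2[-1] == 0

    def test_detection_lag_excludes_same_step(self, default_params):
        traj = cs.simulate_trajectory(default_params, 0.0, 80.0, seed=8)
        onset = cs.simulate_tumor_onset(traj, default_params, seed=9)
        # with a 1-unit lag a transformation in step s is detectable at s+1
        # at the earliest; the first grid point can carry no tumor
        assert onset.new_T1[0] == 0 and onset.new_T2[0] == 0

    def test_onset_probability_matches_path_conditional_oracle(self,
                                                               default_params):
        # For each path, tumors given the path are Poisson with mean equal
        # to the lagged intensity integral; the fraction of paths with a
        # detected tumor must match the mean of 1 - exp(-omega_path).
        p = default_params
        rng = np.random.default_rng(31)
        n_rep = 300
        hits = 0
        expected = np.empty(n_rep)
        for i in range(n_rep):
            traj = cs.simulate_trajectory(p, 0.0, 100.0, rng=rng)
            onset = cs.simulate_tumor_onset(traj, p, rng=rng)
            hits += (onset.T1[-1] + onset.T2[-1]) > 0
            lam1 = p.alpha[-1] * traj.I[:-1, -1].sum() * traj.dt
            lam2 = p.beta[-1] * traj.J[:-1, -1].sum() * traj.dt
            expected[i] = 1.0 - np.exp(-(lam1 + lam2))
        frac = hits / n_rep
        se = np.sqrt(max(expected.mean() * (1 - expected.mean()), 1e-6) / n_rep)
        assert abs(frac - expected.mean()) < 3 * se + 1e-9


class TestSimulateIncidence:
    def test_zero_intensity_zero_cases(self, default_params, seer_table):
        p = default_params.with_updates(lambda_I=0.0, lambda_J=0.0)
        table = cs.simulate_incidence(p, seer_table, seed=2)
        assert np.all(table.y == 0)

    def test_zero_at_risk_gives_zero_cases(self, default_params):
        schedule = [((0.0, 5.0), 0), ((5.0, 10.0), 1000)]
        table = cs.simulate_incidence(default_params, schedule, seed=4)
        assert table.y[0] == 0

    def test_binomial_mean_oracle(self, default_params, seer_table):
        # mean of y_j across seeds matches tau_j = n_j Q_T(j)
        risk = cs.age_group_probabilities(default_params, seer_table)
        tau = seer_table.n * risk.QT
        n_seeds = 60
        j = 10  # 45-49 group
        ys = np.array([cs.simulate_incidence(default_params, seer_table,
                                             seed=s).y[j]
                       for s in range(n_seeds)])
        se = np.sqrt(seer_table.n[j] * risk.QT[j] * (1 - risk.QT[j]) / n_seeds)
        assert abs(ys.mean() - tau[j]) < 3 * se

    def test_provenance_recorded(self, default_params, seer_table):
        table = cs.simulate_incidence(default_params, seer_table, seed=99)
        assert table.provenance["seed"] == 99
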