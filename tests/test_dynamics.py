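"""State assignment and transition kinetics on time series."""

import numpy as np
import pytest

from helimodal import (BinormalSpec, StateTrajectory, TelegraphSpec,
                       assign_states, convergence_profile, fit_binormal,
                       sample_telegraph, transition_stats)

from conftest import make_ensemble


def _converged_fit(mu1=0.0, s1=1.0, mu2=8.0, s2=1.0, p=0.5):
    from helimodal.mixture import BinormalFit

    return BinormalFit(model=BinormalSpec(mu1, s1, mu2, s2, p),
                       loglik=0.0, n=1000, converged=True, n_restarts_used=1)


class TestAssignStates:
    def test_one_sided_data_all_state_one(self):
        series = make_ensemble([-3.0, -2.0, -1.5], times=np.array([0., 1., 2.]))
        traj = assign_states(series, _converged_fit())
        assert np.all(traj.states == 1)

    def test_boundary_value_goes_to_state_one(self):
        fit = _converged_fit()  # symmetric components: boundary at 4.0
        series = make_ensemble([4.0, 4.0], times=np.array([0.0, 1.0]))
        traj = assign_states(series, fit)
        assert traj.boundary == pytest.approx(4.0)
        assert np.all(traj.states == 1)

    def test_nonuniform_timestep_names_offender(self):
        series = make_ensemble([0.0, 1.0, 2.0, 3.0],
                               times=np.array([0.0, 1.0, 2.0, 3.5]))
        with pytest.raises(ValueError, match="frame index 3"):
            assign_states(series, _converged_fit())

    def test_telegraph_recovery_accuracy(self):
        spec = TelegraphSpec(5.0, 5.0, BinormalSpec(0, 1, 8, 1, 0.5), dt=0.001)
        series, truth = sample_telegraph(spec, 100.0, seed=0)
        fit = fit_binormal(series, seed=0)
        traj = assign_states(series, fit)
        agreement = np.mean(traj.states == truth.states)
        assert agreement >= 0.99


class TestTransitionStats:
    def test_frozen_trajectory(self):
        st = transition_stats(StateTrajectory(np.ones(100, dtype=int), dt=0.1))
        assert st.n_transitions == 0 and st.rate_per_ns == 0.0
        assert st.occupancy == (1.0, 0.0)
        assert np.isnan(st.mean_residence[0])  # all dwells censored

    def test_strictly_alternating(self):
        states = np.tile([1, 2], 50)
        st = transition_stats(StateTrajectory(states, dt=0.2))
        assert st.n_transitions == 99
        assert st.rate_per_ns == pytest.approx(1 / 0.2)
        assert st.mean_residence[0] == pytest.approx(0.2)

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(1)
        states = rng.integers(1, 3, size=500)
        a = transition_stats(StateTrajectory(states, dt=0.1))
        b = transition_stats(StateTrajectory(3 - states, dt=0.1))
        assert a.n_transitions == b.n_transitions
        assert a.occupancy == b.occupancy[::-1]

    def test_telegraph_residence_and_occupancy(self):
        k = 5.0
        spec = TelegraphSpec(k, k, BinormalSpec(0, 1, 8, 1, 0.5), dt=0.001)
        _, truth = sample_telegraph(spec, 1000.0, seed=2)
        st = transition_stats(truth)
        assert st.mean_residence[0] == pytest.approx(1 / k, rel=0.05)
        assert st.mean_residence[1] == pytest.approx(1 / k, rel=0.05)
        tau_c = 1.0 / (2 * k)
        se = np.sqrt(0.25 * 2 * tau_c / 1000.0)
        assert abs(st.occupancy[0] - 0.5) < 3 * se
        # alternating-renewal identity: rate ~ 2/(tau1+tau2)
        tau1, tau2 = st.mean_residence
        assert st.rate_per_ns == pytest.approx(2 / (tau1 + tau2), rel=0.05)

    def test_min_dwell_filter_suppresses_recrossings(self):
        states = np.array([1] * 50 + [2] + [1] * 50 + [2] * 50, dtype=int)
        raw = transition_stats(StateTrajectory(states, dt=1.0))
        filt = transition_stats(StateTrajectory(states, dt=1.0), min_dwell=3)
        assert raw.n_transitions == 3
        assert filt.n_transitions == 1


class TestConvergenceProfile:
    def test_single_window_equals_transition_stats(self):
        spec = TelegraphSpec(5.0, 5.0, BinormalSpec(0, 1, 8, 1, 0.5), dt=0.001)
        series, _ = sample_telegraph(spec, 50.0, seed=3)
        fit = fit_binormal(series, seed=3)
        traj = assign_states(series, fit)
        full = transition_stats(traj)
        prof = convergence_profile(series, fit, windows=[traj.duration])
        w, occ_low, rate = prof["windows"][0]
        assert occ_low == pytest.approx(full.occupancy[0])
        assert rate == pytest.approx(full.rate_per_ns)

    def test_stationary_series_longest_window_occupancy(self):
        spec = TelegraphSpec(8.0, 2.0, BinormalSpec(0, 1, 8, 1, 0.5), dt=0.001)
        series, _ = sample_telegraph(spec, 200.0, seed=4)
        fit = fit_binormal(series, seed=4)
        prof = convergence_profile(series, fit, windows=[50.0, 100.0, 200.0 - 0.001])
        occ_low = prof["windows"][-1][1]
        target = spec.occupancy_1()  # 0.2
        tau_c = 1.0 / 10.0
        se = np.sqrt(target * (1 - target) * 2 * tau_c / 200.0)
        assert abs(occ_low - target) < 3 * se

    def test_burn_in_biases_short_windows(self):
        # slow chain started in the minor state: the short window must
        # over-represent it relative to the long window
        rng = np.random.default_rng(5)
        n = 200_000
        dt = 0.001
        p12 = 1 - np.exp(-0.2 * dt)   # slow leave from minor state 1
        p21 = 1 - np.exp(-0.02 * dt)  # much slower return
        states = np.empty(n, dtype=np.int8)
        states[0] = 1
        u = rng.random(n)
        for t in range(1, n):
            if states[t - 1] == 1:
                states[t] = 2 if u[t] < p12 else 1
            else:
                states[t] = 1 if u[t] < p21 else 2
        x = np.where(states == 1, -4.0, 4.0) + rng.normal(0, 1, n)
        series = make_ensemble(x, times=np.arange(n) * dt)
        fit = _converged_fit(-4.0, 1.0, 4.0, 1.0, 0.5)
        prof = convergence_profile(series, fit, windows=[5.0, (n - 1) * dt])
        occ_short = prof["windows"][0][1]
        occ_long = prof["windows"][-1][1]
        assert occ_short > occ_long  # initial-state bias at short windows

    def test_window_exceeding_duration_raises(self):
        spec = TelegraphSpec(5.0, 5.0, BinormalSpec(0, 1, 8, 1, 0.5), dt=0.001)
        series, _ = sample_telegraph(spec, 10.0, seed=6)
        fit = fit_binormal(series, seed=6)
        with pytest.raises(ValueError, match="exceeds"):
            convergence_profile(series, fit, windows=[100.0])

    def test_occupancies_sum_to_one_per_window(self):
        spec = TelegraphSpec(5.0, 5.0, BinormalSpec(0, 1, 8, 1, 0.5), dt=0.001)
        series, _ = sample_telegraph(spec, 20.0, seed=7)
        fit = fit_binormal(series, seed=7)
        traj = assign_states(series, fit)
        for w in (5.0, 10.0):
            m = int(round(w / traj.dt)) + 1
            st = transition_stats(StateTrajectory(traj.states[:m], dt=traj.dt))
            assert sum(st.occupancy) == pytest.approx(1.0)
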