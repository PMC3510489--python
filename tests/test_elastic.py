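"""Stiffness estimation and the two-state elastic energy surface."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helimodal import (BimodalElastic, BinormalSpec, ElasticState,
                       HarmonicSpec, TelegraphSpec, delta_g_from_mixture,
                       energy_harmonic, energy_smooth, energy_two_state,
                       fit_binormal, per_state_split, required_state_count,
                       sample_binormal, sample_harmonic, sample_telegraph,
                       stiffness_from_covariance, unimodal_error_profile)
from helimodal.elastic import MultiStateElastic, RankError
from helimodal.mixture import BinormalFit


def _state_1d(x0=0.0, k=1.0):
    return ElasticState(x0=np.array([x0]), stiffness=np.array([[k]]))


class TestStiffnessFromCovariance:
    def test_roundtrip_identity_stiffness(self):
        spec = HarmonicSpec(np.zeros(6), np.eye(6))
        x = sample_harmonic(spec, 100_000, seed=0)
        est = stiffness_from_covariance(x)
        np.testing.assert_allclose(est.stiffness, np.eye(6), atol=0.05)

    def test_one_dimensional_k_is_kt_over_var(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 2.0, size=(5000, 1))
        x = (x - x.mean()) / x.std(ddof=1) * 2.0  # variance exactly 4
        est = stiffness_from_covariance(x, kT=1.0)
        assert est.stiffness[0, 0] == pytest.approx(0.25, abs=1e-12)

    def test_collinear_coordinates_raise_rank_error(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=1000)
        x = np.column_stack([a, 2 * a, rng.normal(size=1000)])
        with pytest.raises(RankError, match="collinear"):
            stiffness_from_covariance(x)

    def test_needs_enough_samples(self):
        with pytest.raises(ValueError, match="10·d"):
            stiffness_from_covariance(np.random.default_rng(0).normal(size=(50, 6)))


class TestEnergyHarmonic:
    def test_zero_at_equilibrium(self):
        st6 = ElasticState(x0=np.arange(6.0), stiffness=np.eye(6))
        assert energy_harmonic(st6, np.arange(6.0)) == 0.0

    def test_scalar_case(self):
        assert energy_harmonic(_state_1d(k=0.05), np.array([10.0])) == \
            pytest.approx(2.5)

    @given(v=st.lists(st.floats(-10, 10), min_size=3, max_size=3))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_harmonic_symmetry(self, v):
        st3 = ElasticState(x0=np.ones(3), stiffness=np.eye(3) * 2.0)
        v = np.asarray(v)
        assert energy_harmonic(st3, st3.x0 + v) == pytest.approx(
            energy_harmonic(st3, st3.x0 - v), rel=1e-12, abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            energy_harmonic(_state_1d(), np.array([1.0, 2.0]))


class TestEnergyTwoState:
    def test_branch_minimum_at_state_i(self):
        model = BimodalElastic(_state_1d(0.0), _state_1d(4.0), delta_g_ij=1.0)
        e_i, e_j, e_min = energy_two_state(model, np.array([0.0]))
        assert e_i == 0.0 and e_min == 0.0

    def test_branch_j_minimum_is_delta_g(self):
        model = BimodalElastic(_state_1d(0.0), _state_1d(4.0), delta_g_ij=1.0)
        e_i, e_j, e_min = energy_two_state(model, np.array([4.0]))
        assert e_j == pytest.approx(1.0)
        assert e_min <= e_i

    def test_symmetric_crossing_at_midpoint(self):
        model = BimodalElastic(_state_1d(-2.0), _state_1d(2.0), delta_g_ij=0.0)
        e_i, e_j, _ = energy_two_state(model, np.array([0.0]))
        assert e_i == pytest.approx(e_j)


class TestEnergySmooth:
    def test_value_at_crossing_is_e_minus_eps(self):
        eps = 0.3
        model = BimodalElastic(_state_1d(-2.0), _state_1d(2.0), epsilon=eps)
        e_i, _, _ = energy_two_state(model, np.array([0.0]))
        assert energy_smooth(model, np.array([0.0])) == pytest.approx(e_i - eps)

    def test_converges_to_hard_minimum_as_eps_vanishes(self):
        model = BimodalElastic(_state_1d(-2.0), _state_1d(2.0),
                               delta_g_ij=0.5, epsilon=1e-6)
        xs = np.linspace(-6, 6, 241)
        for x in xs:
            _, _, e_min = energy_two_state(model, np.array([x]))
            assert abs(energy_smooth(model, np.array([x])) - e_min) < 1e-5

    def test_below_hard_minimum_with_gap_at_most_eps(self):
        eps = 0.25
        model = BimodalElastic(_state_1d(-1.5, 2.0), _state_1d(1.5, 0.5),
                               delta_g_ij=0.8, epsilon=eps)
        for x in np.linspace(-5, 5, 101):
            _, _, e_min = energy_two_state(model, np.array([x]))
            e_s = energy_smooth(model, np.array([x]))
            assert e_s <= e_min + 1e-12
            assert e_min - e_s <= eps + 1e-12

    def test_gradient_smooth_across_crossing(self):
        eps = 0.1
        model = BimodalElastic(_state_1d(-2.0), _state_1d(2.0), epsilon=eps)
        h = 1e-4
        xs = np.arange(-0.01, 0.01, h)
        grads = [(energy_smooth(model, np.array([x + h]))
                  - energy_smooth(model, np.array([x - h]))) / (2 * h)
                 for x in xs]
        jumps = np.abs(np.diff(grads))
        assert jumps.max() < 10 * eps * h / 1e-4  # no kink at the crossing

    @given(shift=st.floats(-20, 20))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_translation_invariance(self, shift):
        m0 = BimodalElastic(_state_1d(-1.0), _state_1d(1.0), delta_g_ij=0.3)
        m1 = BimodalElastic(_state_1d(-1.0 + shift), _state_1d(1.0 + shift),
                            delta_g_ij=0.3)
        x = 0.37
        assert energy_smooth(m0, np.array([x])) == pytest.approx(
            energy_smooth(m1, np.array([x + shift])), rel=1e-9, abs=1e-9)


class TestDeltaG:
    def test_equal_populations(self):
        fit = _fit_with_p(0.5)
        assert delta_g_from_mixture(fit) == 0.0

    def test_log_identity(self):
        p = np.e / (1 + np.e)  # population ratio e -> exactly 1 kT
        assert delta_g_from_mixture(_fit_with_p(p)) == pytest.approx(1.0)

    def test_boltzmann_roundtrip_through_telegraph(self):
        # rates chosen so occupancies obey the target delta G; the simulated
        # populations must invert back to it
        dg = 0.8  # kT
        k21 = 4.0
        k12 = k21 * np.exp(-dg)  # detailed balance: occ1/occ2 = exp(dg)
        spec = TelegraphSpec(k12, k21, BinormalSpec(0, 1, 8, 1, 0.5), dt=0.005)
        # ~10^5 dwell cycles so the occupancy SE supports a 5% check on dg
        _, truth = sample_telegraph(spec, 16_000.0, seed=3)
        occ1 = float(np.mean(truth.states == 1))
        dg_est = -np.log((1 - occ1) / occ1)
        assert dg_est == pytest.approx(dg, rel=0.05)


def _fit_with_p(p):
    model = BinormalSpec(0.0, 1.0, 4.0, 1.0, p)
    return BinormalFit(model=model, loglik=0.0, n=100, converged=True,
                       n_restarts_used=1)


class TestPerStateSplit:
    def test_well_separated_assignment_accuracy(self):
        rng = np.random.default_rng(4)
        n = 4000
        truth = rng.random(n) < 0.5
        x = np.where(truth, rng.normal(0, 1, n), rng.normal(8, 1, n))
        joint = np.column_stack([x, rng.normal(size=n)])
        fit = fit_binormal(x, seed=4)
        part_i, part_j = per_state_split(joint, fit, split_parameter=0)
        # accuracy vs the Bayes-optimal boundary at the midpoint
        acc = (np.sum(part_i[:, 0] < 4.0) + np.sum(part_j[:, 0] >= 4.0)) / n
        assert acc >= 0.99

    def test_split_sizes_near_half_for_symmetric_data(self):
        rng = np.random.default_rng(5)
        n = 10_000
        comp = rng.random(n) < 0.5
        x = np.where(comp, rng.normal(-3, 1, n), rng.normal(3, 1, n))
        joint = x.reshape(-1, 1)
        fit = fit_binormal(x, seed=5)
        part_i, _ = per_state_split(joint, fit)
        se = 0.5 * np.sqrt(n)
        assert abs(part_i.shape[0] - n / 2) < 4 * se

    def test_insufficient_state_data_raises(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(0, 1, 2000), rng.normal(10, 1, 5)])
        fit = fit_binormal(x, seed=6)
        with pytest.raises(ValueError, match="state j"):
            per_state_split(x.reshape(-1, 1), fit)


class TestUnimodalErrorProfile:
    def test_barrier_top_underestimated_by_unimodal_fit(self):
        # symmetric wells at +-2 with the unimodal fit centred on the barrier
        model = BimodalElastic(_state_1d(-2.0, 1.0), _state_1d(2.0, 1.0),
                               epsilon=0.1)
        # unimodal sigma inflated by bimodality: var = sigma^2 + a^2
        sigma_mix2 = 1.0 + 4.0
        uni = ElasticState(x0=np.array([0.0]),
                           stiffness=np.array([[1.0 / sigma_mix2]]))
        prof = unimodal_error_profile(uni, model, np.linspace(-6, 6, 121))
        mid = prof[np.argmin(np.abs(prof[:, 0]))]
        assert mid[3] > 0  # e_bi > e_uni at the unimodal minimum
        # at the true well bottoms the unimodal model charges energy
        at_mode = prof[np.argmin(np.abs(prof[:, 0] + 2.0))]
        assert at_mode[1] > 0 and abs(at_mode[2]) < 0.15

    def test_tail_curvature_comparison(self):
        # inflated unimodal sigma means too-small tail penalty:
        # kT/sigma_mix^2 < kT/sigma_i^2 shows up far from the wells
        model = BimodalElastic(_state_1d(-2.0, 1.0), _state_1d(2.0, 1.0),
                               epsilon=0.1)
        uni = ElasticState(x0=np.array([0.0]), stiffness=np.array([[1 / 5.0]]))
        prof = unimodal_error_profile(uni, model, np.array([8.0, -8.0]))
        assert np.all(prof[:, 1] < prof[:, 2])


class TestStateCountScaling:
    @pytest.mark.parametrize("n,expected", [(1, 1), (2, 2), (3, 4)])
    def test_two_power_scaling(self, n, expected):
        assert required_state_count(n) == expected

    def test_container_enforces_count(self):
        s = _state_1d()
        MultiStateElastic(states=(s, s), n_bimodal=2)
        with pytest.raises(ValueError, match="require"):
            MultiStateElastic(states=(s, s, s), n_bimodal=2)
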