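"""Growth laws, viability-modified net dynamics, and the Bernoulli oracle."""

import math

import numpy as np
import pytest

from regrowth import (
    ConfigurationError,
    DomainError,
    GrowthLawParams,
    RegrowthModel,
    exponential_blowup_time,
    exponential_burden_at,
    exponential_recurrence_time,
    growth_rate,
    net_rate,
    simulate_trajectory,
)

LAWS = ["exponential", "logistic", "gompertz"]


def _params(law, lam=1.0, K=13.8):
    return GrowthLawParams(law, lam, K if law != "exponential" else None)


class TestGrowthRate:
    def test_logistic_attenuation_near_exponential(self):
        # at V far below K the logistic rate is (1 - V/K) of the exponential one
        p = _params("logistic")
        assert growth_rate(p, 0.056) / (1.0 * 0.056) == pytest.approx(0.996, abs=5e-4)

    @pytest.mark.parametrize("law", LAWS)
    def test_extinction_fixed_point(self, law):
        assert growth_rate(_params(law), 0.0) == 0.0

    def test_gompertz_log_factor(self):
        p = _params("gompertz")
        assert growth_rate(p, 0.056) / 0.056 == pytest.approx(math.log(13.8 / 0.056), rel=1e-12)
        assert growth_rate(p, 0.056) / 0.056 == pytest.approx(5.507, abs=5e-3)

    def test_gompertz_above_capacity_is_negative(self):
        assert growth_rate(_params("gompertz"), 20.0) < 0

    def test_negative_volume_rejected(self):
        with pytest.raises(DomainError):
            growth_rate(_params("exponential"), -1.0)

    def test_capacity_required_for_bounded_laws(self):
        with pytest.raises(ConfigurationError):
            GrowthLawParams("logistic", 1.0)


class TestNetRate:
    def test_equilibrium_at_eps_V(self):
        m = RegrowthModel(GrowthLawParams("exponential", 0.0015), 0.01, 0.056)
        assert net_rate(m, 0.01) == 0.0

    def test_hand_evaluated_values(self):
        m = RegrowthModel(GrowthLawParams("exponential", 0.0015), 0.01, 0.056)
        assert net_rate(m, 0.02) == pytest.approx(3.0e-5, rel=1e-12)
        assert net_rate(m, 0.005) == pytest.approx(-3.75e-6, rel=1e-12)

    @pytest.mark.parametrize("law", LAWS)
    def test_sign_structure_with_viability(self, law):
        # negative iff 0 < B < eps_V; zero at {0, eps_V}; positive above
        m = RegrowthModel(_params(law, lam=0.001), 0.01, 0.056)
        assert net_rate(m, 0.0) == 0.0
        assert net_rate(m, 0.01) == pytest.approx(0.0, abs=1e-18)
        for B in np.linspace(1e-4, 0.0099, 20):
            assert net_rate(m, float(B)) < 0
        for B in np.linspace(0.0101, 1.0, 20):
            assert net_rate(m, float(B)) > 0

    @pytest.mark.parametrize("law", LAWS)
    def test_nonnegative_without_viability_term(self, law):
        m = RegrowthModel(_params(law, lam=0.001), 0.01, 0.056, viability_term_enabled=False)
        for B in np.linspace(0.0, 13.8, 30):
            assert net_rate(m, float(B)) >= 0

    def test_zero_eps_V_with_viability_is_config_error(self):
        m = RegrowthModel(GrowthLawParams("exponential", 0.001), 0.0, 0.056)
        with pytest.raises(ConfigurationError, match="disable the viability term"):
            net_rate(m, 0.02)


class TestClosedForm:
    def test_fixed_point_and_initial_condition(self):
        assert exponential_burden_at(0.01, 0.0015, 0.01, 500.0) == pytest.approx(0.01)
        assert exponential_burden_at(0.02, 0.0015, 0.01, 0.0) == pytest.approx(0.02)

    def test_detection_crossing_value(self):
        # the burden reaching the detection threshold at the closed-form time
        assert exponential_burden_at(0.02, 0.0015, 0.01, 330.96) == pytest.approx(0.056, abs=1e-4)

    def test_matches_small_step_euler(self):
        # independent brute-force check of the Bernoulli solution
        B0, lam, eps = 0.02, 0.0015, 0.01
        dt, B, t_end = 0.001, B0, 331.0
        n = int(t_end / dt)
        for _ in range(n):
            B += dt * lam * B * (B / eps - 1.0)
        assert exponential_burden_at(B0, lam, eps, n * dt) == pytest.approx(B, rel=1e-5)

    def test_blowup_time_is_a_domain_error(self):
        t_star = exponential_blowup_time(0.02, 0.0015, 0.01)
        with pytest.raises(DomainError, match="blow-up"):
            exponential_burden_at(0.02, 0.0015, 0.01, t_star + 1.0)

    def test_recurrence_time_examples(self):
        assert exponential_recurrence_time(0.056, 1.0, 0.01, 0.056) == 0.0
        assert exponential_recurrence_time(0.02, 0.0015, 0.01, 0.056) == pytest.approx(331.0, abs=0.1)
        assert exponential_recurrence_time(0.005, 0.0015, 0.01, 0.056) is None

    def test_recurrence_time_diverges_near_eps_V(self):
        # crossing time grows without bound as B0 approaches eps_V from above
        t = exponential_recurrence_time(0.01001, 0.0015, 0.01, 0.056)
        assert t > 3000
        t2 = exponential_recurrence_time(0.010001, 0.0015, 0.01, 0.056)
        assert t2 > t


class TestTrajectory:
    def test_equilibrium_trajectory_constant(self):
        m = RegrowthModel(GrowthLawParams("exponential", 0.0008), 0.01, 0.056)
        tr = simulate_trajectory(m, 0.01, np.linspace(0, 1000, 50))
        assert np.allclose(tr.burdens, 0.01, rtol=1e-8)

    def test_subthreshold_decays_to_zero(self):
        m = RegrowthModel(GrowthLawParams("exponential", 0.0015), 0.01, 0.056)
        tr = simulate_trajectory(m, 0.005, np.linspace(0, 20000, 100))
        assert tr.burdens[-1] < 1e-6
        assert np.all(np.diff(tr.burdens) <= 1e-12)

    def test_matches_closed_form_at_named_time(self):
        m = RegrowthModel(GrowthLawParams("exponential", 0.0015), 0.01, 0.056)
        tr = simulate_trajectory(m, 0.02, np.array([0.0, 331.0]))
        assert tr.burdens[-1] == pytest.approx(0.056, abs=2e-4)

    def test_oracle_equivalence_random_parameters(self, rng):
        # ODE vs exact Bernoulli solution over 100 random parameter sets
        for _ in range(100):
            eps = float(rng.uniform(0.001, 0.02))
            omega = eps * float(rng.uniform(2.0, 10.0))
            B0 = float(rng.uniform(eps * 1.05, omega * 0.95))
            lam = float(rng.uniform(5e-4, 5e-3))
            m = RegrowthModel(GrowthLawParams("exponential", lam), eps, omega)
            t_cross = exponential_recurrence_time(B0, lam, eps, omega)
            grid = np.linspace(0.0, 0.95 * t_cross, 20)
            tr = simulate_trajectory(m, B0, grid)
            exact = exponential_burden_at(B0, lam, eps, grid)
            assert np.max(np.abs(tr.burdens - exact) / exact) < 1e-6

    def test_blowup_truncates_with_flag(self):
        m = RegrowthModel(GrowthLawParams("exponential", 0.0015), 0.01, 0.056)
        t_star = exponential_blowup_time(0.02, 0.0015, 0.01)
        tr = simulate_trajectory(m, 0.02, np.linspace(0, 2 * t_star, 200))
        assert tr.truncated
        assert tr.times[-1] < 2 * t_star
        assert np.all(np.isfinite(tr.burdens))

    def test_nonfinite_b0_rejected(self):
        m = RegrowthModel(GrowthLawParams("exponential", 0.0015), 0.01, 0.056)
        with pytest.raises(DomainError):
            simulate_trajectory(m, float("nan"), np.array([0.0, 1.0]))


class TestLimits:
    def test_logistic_approaches_exponential_at_large_K(self, rng):
        # recurrence times agree within 1% when K >= 1000 * omega_d
        from regrowth import patient_recurrence_time

        lam, eps, omega = 0.0015, 0.01, 0.056
        m_exp = RegrowthModel(GrowthLawParams("exponential", lam), eps, omega)
        m_log = RegrowthModel(GrowthLawParams("logistic", lam, 1000 * omega), eps, omega)
        for B0 in [0.015, 0.02, 0.03, 0.05]:
            t_e = patient_recurrence_time(B0, m_exp).t_R
            t_l = patient_recurrence_time(B0, m_log).t_R
            assert abs(t_l - t_e) / t_e < 0.01

    def test_gompertz_recurs_strictly_faster(self):
        # superexponential factor ln(K/V) > 1 over the whole transit
        from regrowth import patient_recurrence_time

        lam, eps, omega, K = 0.0009, 0.015, 0.056, 13.8
        m_exp = RegrowthModel(GrowthLawParams("exponential", lam), eps, omega)
        m_gom = RegrowthModel(GrowthLawParams("gompertz", lam, K), eps, omega)
        for B0 in [0.018, 0.02, 0.03, 0.05]:
            t_e = patient_recurrence_time(B0, m_exp).t_R
            t_g = patient_recurrence_time(B0, m_gom).t_R
            assert t_g < t_e
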