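import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

from thermorad.model_core import (
    ModelParams,
    State,
    heaviside,
    ht_damage_rate,
    lambda_closed_form,
    repair_rate,
    rhs,
    rhs_autonomous,
    rt_dose_rate,
)
from thermorad.schedules import (
    build_combined,
    build_ht_schedule,
    build_rt_schedule,
    null_schedule,
)


class TestHeaviside:
    def test_zero_is_one(self):
        assert heaviside(0.0) == 1

    def test_negative_is_zero(self):
        assert heaviside(-0.5) == 0

    def test_positive_is_one(self):
        assert heaviside(3.0) == 1

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), -float("inf")])
    def test_non_finite_rejected(self, bad):
        with pytest.raises(ValueError):
            heaviside(bad)

    @given(st.floats(allow_nan=False, allow_infinity=False))
    def test_binary_and_monotone(self, x):
        h = heaviside(x)
        assert h in (0, 1)
        assert h == (1 if x >= 0 else 0)


class TestForcing:
    def test_rt_rate_inside_window(self):
        s = build_rt_schedule(2.0, 5)
        assert rt_dose_rate(5.0, s) == pytest.approx(0.2)

    def test_rt_rate_outside_window(self):
        s = build_rt_schedule(2.0, 5)
        assert rt_dose_rate(500.0, s) == 0.0

    def test_rt_rate_dose_five(self):
        s = build_rt_schedule(5.0, 1)
        assert rt_dose_rate(0.0, s) == pytest.approx(0.5)

    def test_rt_window_endpoints_closed(self):
        s = build_rt_schedule(2.0, 5)
        assert rt_dose_rate(0.0, s) == pytest.approx(0.2)
        assert rt_dose_rate(10.0, s) == pytest.approx(0.2)
        assert rt_dose_rate(10.0 + 1e-9, s) == 0.0

    def test_ht_rate_inside_window(self):
        s = build_ht_schedule(0.005, 8)
        assert ht_damage_rate(30.0, s) == pytest.approx(0.005)

    def test_ht_rate_before_first_window(self):
        s = build_combined(2.0, 5, 0.005)  # HT starts at t = 11
        assert ht_damage_rate(5.0, s) == 0.0

    def test_ht_rate_null_modality(self):
        s = build_rt_schedule(2.0, 5)
        for t in (0.0, 11.0, 5000.0):
            assert ht_damage_rate(t, s) == 0.0


class TestLambdaClosedForm:
    K1, K2, DH = 0.5, 1e-3, 60.0

    def test_zero_before_fraction(self):
        assert lambda_closed_form(5.0, 10.0, self.DH, self.K1, self.K2) == 0.0

    def test_decays_to_zero(self):
        val = lambda_closed_form(1e7, 0.0, self.DH, self.K1, self.K2)
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_value_at_end_of_fraction(self):
        # independent scalar oracle: (k1/(k1+k2)) * (1 - exp(-(k1+k2)*dH))
        expected = (self.K1 / (self.K1 + self.K2)) * (
            1.0 - math.exp(-(self.K1 + self.K2) * self.DH)
        )
        assert expected == pytest.approx(0.998004, abs=5e-7)
        got = lambda_closed_form(self.DH, 0.0, self.DH, self.K1, self.K2)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_matches_ode_integration_oracle(self):
        """Numerical integration of dL/dt = k1*1_HT*(1-L) - k2*L."""

        def ode(t, y):
            drive = self.K1 if 0.0 <= t <= self.DH else 0.0
            return [drive * (1.0 - y[0]) - self.K2 * y[0]]

        t_eval = np.linspace(0.0, 300.0, 200)
        sol_a = solve_ivp(ode, (0.0, self.DH), [0.0], rtol=1e-11, atol=1e-13,
                          t_eval=t_eval[t_eval <= self.DH])
        sol_b = solve_ivp(ode, (self.DH, 300.0), sol_a.y[:, -1],
                          rtol=1e-11, atol=1e-13,
                          t_eval=t_eval[t_eval >= self.DH])
        ts = np.concatenate([sol_a.t, sol_b.t])
        ys = np.concatenate([sol_a.y[0], sol_b.y[0]])
        expect = [lambda_closed_form(t, 0.0, self.DH, self.K1, self.K2)
                  for t in ts]
        np.testing.assert_allclose(ys, expect, atol=1e-8)

    @pytest.mark.parametrize("t", [0.0, 60.0])
    def test_continuity_at_breakpoints(self, t):
        lo = lambda_closed_form(t - 1e-9, 0.0, self.DH, self.K1, self.K2)
        hi = lambda_closed_form(t + 1e-9, 0.0, self.DH, self.K1, self.K2)
        assert lo == pytest.approx(hi, abs=1e-8)

    def test_rejects_nonpositive_rates(self):
        with pytest.raises(ValueError):
            lambda_closed_form(1.0, 0.0, 60.0, 0.0, 1e-3)


class TestRepairRate:
    def test_baseline(self):
        assert repair_rate(0.0, 5e-3, 2.5) == pytest.approx(5e-3)

    def test_fully_inhibited(self):
        # independent computation: 0.005 * e^-2.5
        assert repair_rate(1.0, 5e-3, 2.5) == pytest.approx(
            5e-3 * math.exp(-2.5), rel=1e-12
        )
        assert repair_rate(1.0, 5e-3, 2.5) == pytest.approx(4.104e-4, abs=5e-7)

    @given(st.floats(0.0, 1.0))
    def test_no_weight_means_baseline(self, lam):
        assert repair_rate(lam, 5e-3, 0.0) == pytest.approx(5e-3)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_strictly_decreasing(self, a, b):
        lo, hi = sorted((a, b))
        r_lo = repair_rate(lo, 5e-3, 2.5)
        r_hi = repair_rate(hi, 5e-3, 2.5)
        assert r_hi <= r_lo
        if hi - lo > 1e-12:  # below float resolution exp(-x) rounds to 1
            assert r_hi < r_lo

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            repair_rate(1.5, 5e-3, 2.5)


class TestModelParams:
    def test_derived_relations(self, params):
        p = params.for_tumour(q1=0.5, q3=2.0)
        assert p.q2 == pytest.approx(p.k * p.q3)
        assert p.delta == p.q2
        assert p.delta_S == pytest.approx(p.theta2 * p.q2)

    def test_reference_values(self, params):
        assert params.c_min == 1e-2
        assert params.g == 5.0
        assert params.mu0 == 5e-3
        assert params.xi == 5e-4
        assert params.kappa0 == 1e-7
        assert params.eta_R == params.eta_H == 5e-5
        assert params.mu_Lambda == 2.5
        assert params.k2 == 1e-3

    def test_with_beta_sets_k1(self, params):
        assert params.with_beta(0.005).k1 == pytest.approx(0.5)
        assert params.with_beta(0.0).k1 == 0.0

    def test_mapping_round_trip(self, params):
        p = params.for_tumour(1.23, 4.56)
        assert ModelParams.from_mapping(p.to_mapping()) == p

    def test_mapping_excludes_derived(self, params):
        m = params.to_mapping()
        for key in ("q2", "delta", "delta_S", "k1"):
            assert key not in m
        with pytest.raises(ValueError):
            ModelParams.from_mapping({"q2": 0.01})

    @pytest.mark.parametrize(
        "kwargs",
        [{"c_min": 1.5}, {"theta2": 1.2}, {"theta1": 0.5}, {"g": -1.0}],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs).validate()


class TestRhs:
    def test_fixed_point_gives_zero(self, representatives):
        t = representatives["A2"]
        y = np.array([t.T_star, 0, 0, 0, t.V0, t.c_star, 0.0])
        dy = rhs(0.0, y, t.params(), null_schedule())
        np.testing.assert_allclose(dy, 0.0, atol=1e-12)

    def test_zero_state_gives_zero(self, params):
        dy = rhs(0.0, np.zeros(7), params, build_combined(2.0, 5, 0.005))
        np.testing.assert_allclose(dy, 0.0, atol=0.0)

    def test_hand_evaluated_growth_term(self, params):
        # T=0.5, V=0.005, c=0.5, q3=1 (q2=0.01), no treatment:
        # dT/dt = 0.01 * 0.5 * (1 - 0.505) * 0.5
        p = params.for_tumour(q1=0.0, q3=1.0)
        y = np.array([0.5, 0, 0, 0, 0.005, 0.5, 0.0])
        dy = rhs(0.0, y, p, null_schedule())
        assert dy[0] == pytest.approx(1.2375e-3, rel=1e-12)

    def test_schedule_lookup_matches_autonomous(self, representatives):
        t = representatives["A2"]
        p = t.params().with_beta(0.005)
        s = build_combined(2.0, 5, 0.005)
        y = np.array([0.4, 0.05, 0.01, 0.02, 0.005, 0.3, 0.1])
        # inside the Monday RT window
        np.testing.assert_allclose(
            rhs(5.0, y, p, s), rhs_autonomous(y, p, 0.2, 0.0, False)
        )
        # inside the Monday HT window [11, 71]
        np.testing.assert_allclose(
            rhs(40.0, y, p, s), rhs_autonomous(y, p, 0.0, 0.005, True)
        )

    def test_numba_kernel_matches_reference(self, representatives):
        from thermorad.simulate import _kernel_and_args

        t = representatives["C2"]
        p = t.params().with_beta(0.005)
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.uniform(0.0, 0.3, size=7)
            for R, beta, ht_on in ((0.0, 0.0, False), (0.2, 0.0, False),
                                   (0.0, 0.005, True), (0.5, 0.01, True)):
                kernel, args = _kernel_and_args(p, R, beta, ht_on)
                np.testing.assert_allclose(
                    kernel(0.0, y, *args),
                    rhs_autonomous(y, p, R, beta, ht_on),
                    rtol=1e-14,
                )

    def test_oxygen_bounds_preserved(self, params):
        # dc/dt <= 0 at c = 1 and >= 0 at c = 0 keeps c in [0, 1]
        p = params.for_tumour(1.0, 1.0)
        y_hi = np.array([0.5, 0.1, 0.0, 0.0, 0.005, 1.0, 0.0])
        y_lo = np.array([0.5, 0.1, 0.0, 0.0, 0.005, 0.0, 0.0])
        assert rhs_autonomous(y_hi, p, 0.0, 0.0, False)[5] <= 0
        assert rhs_autonomous(y_lo, p, 0.0, 0.0, False)[5] >= 0


class TestState:
    def test_sigma_and_round_trip(self):
        s = State(T=0.5, T_S=0.1, T_R=0.05, T_H=0.02, V=0.005, c=0.3,
                  Lambda=0.1)
        assert s.sigma == pytest.approx(0.675)
        assert State.from_array(s.to_array()) == s
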