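import numpy as np
import pytest
from scipy.optimize import brentq

from thermorad.equilibria import (
    NoRootError,
    RegimeLabel,
    classify_regime,
    nl_candidates,
    nl_fixed_point,
    q1_threshold,
    q3_threshold,
    sl_fixed_point,
)
from thermorad.model_core import ModelParams, rhs
from thermorad.schedules import null_schedule
from thermorad.simulate import SolverOptions, simulate_state


def _oxygen_balance_residual(c, T, q1, q3, V0, p):
    free = 1.0 - T - V0
    return p.g * (1.0 - c) * V0 - (q1 * c * T + q3 * c * free * T)


class TestSLFixedPoint:
    def test_tumour_volume_is_one_minus_v0(self):
        fp = sl_fixed_point(0.151, 0.210, 0.005)
        assert fp.T_star == pytest.approx(0.995)

    def test_oxygen_from_root_finder_oracle(self, params):
        fp = sl_fixed_point(0.151, 0.210, 0.005, params)
        # oracle: scalar root of the oxygen balance at full occupancy
        c_oracle = brentq(
            _oxygen_balance_residual, 1e-12, 1.0,
            args=(0.995, 0.151, 0.210, 0.005, params), xtol=1e-14,
        )
        assert c_oracle == pytest.approx(0.14266, abs=1e-5)
        assert fp.c_star == pytest.approx(c_oracle, rel=1e-10)

    def test_hypoxic_branch_rejected(self, params):
        # q1 = 10 drives c* ~ 0.0025 < c_min
        assert sl_fixed_point(10.0, 0.210, 0.005, params) is None

    def test_t_star_independent_of_consumption(self, params):
        for q1, q3 in [(0.05, 0.1), (1.0, 5.0), (2.0, 0.02)]:
            fp = sl_fixed_point(q1, q3, 0.005, params)
            assert fp is not None and fp.T_star == pytest.approx(0.995)


class TestNLFixedPoint:
    def test_representative_nl_tumour(self, params):
        fp = nl_fixed_point(0.503, 0.272, 0.0005, params)
        assert fp is not None and fp.stable
        assert 0.0 < fp.c_star < params.c_min

    def test_starvation_limit_monotone(self, params):
        t_stars = []
        for q1 in np.geomspace(0.3, 300.0, 12):
            fp = nl_fixed_point(q1, 0.272, 0.0005, params)
            assert fp is not None
            t_stars.append(fp.T_star)
        assert all(a > b for a, b in zip(t_stars, t_stars[1:]))
        assert t_stars[-1] < 0.01

    @pytest.mark.parametrize(
        "q1,q3,V0",
        [(0.503, 0.272, 0.0005), (7.78, 0.0401, 0.0005), (7.60, 9.94, 0.0005)],
    )
    def test_root_residual(self, q1, q3, V0, params):
        fp = nl_fixed_point(q1, q3, V0, params)
        y = np.array([fp.T_star, 0, 0, 0, V0, fp.c_star, 0.0])
        dy = rhs(0.0, y, params.for_tumour(q1, q3), null_schedule())
        assert np.abs(dy).max() < 1e-10

    def test_matches_grid_root_finder_oracle(self, params):
        """Independent oracle: nested scalar root-finding on the reduced
        untreated system, bracketed on a T grid."""
        q1, q3, V0 = 7.60, 9.94, 0.0005
        p = params.for_tumour(q1, q3)

        def balance(T):
            c = brentq(
                _oxygen_balance_residual, 1e-14, 1.0,
                args=(T, q1, q3, V0, p), xtol=1e-15,
            )
            # proliferation = hypoxic death (delta = q2 cancels):
            return c * (1.0 - T - V0) - (p.c_min - c)

        fp = nl_fixed_point(q1, q3, V0, params)
        grid = np.linspace(1e-6, 1.0 - V0 - 1e-6, 400)
        vals = [balance(T) for T in grid]
        roots = [
            brentq(balance, a, b, xtol=1e-14)
            for a, b, va, vb in zip(grid, grid[1:], vals, vals[1:])
            if va * vb < 0
        ]
        assert any(abs(r - fp.T_star) < 1e-8 for r in roots)


class TestClassify:
    def test_sl_fixture(self):
        assert classify_regime(0.151, 0.210, 0.005) is RegimeLabel.SL

    def test_nl_fixture(self):
        assert classify_regime(0.503, 0.272, 0.0005) is RegimeLabel.NL

    def test_all_representatives(self, representatives):
        for name, t in representatives.items():
            expected = RegimeLabel.NL if name.endswith("1") else RegimeLabel.SL
            assert t.regime is expected

    def test_above_q1_threshold_always_nl(self, params):
        q1_bar = q1_threshold(0.005, params)
        for q3 in (0.02, 0.5, 4.0, 9.9):
            assert classify_regime(q1_bar * 1.05, q3, 0.005) is RegimeLabel.NL

    def test_bs_triple(self):
        assert classify_regime(1.0, 9.0, 0.00275) is RegimeLabel.BS


class TestQ1Threshold:
    @pytest.mark.parametrize(
        "V0,expected", [(0.005, 2.4874), (0.0005, 0.24762)]
    )
    def test_reference_values(self, V0, expected, params):
        assert q1_threshold(V0, params) == pytest.approx(expected, abs=1e-4)

    @pytest.mark.parametrize("V0", [0.0005, 0.00275, 0.005])
    def test_closed_form_oracle(self, V0, params):
        analytic = (
            params.g * V0 * (1.0 - params.c_min)
            / ((1.0 - V0) * params.c_min)
        )
        assert q1_threshold(V0, params) == pytest.approx(analytic, rel=1e-10)

    def test_bisection_on_admissibility_oracle(self, params):
        """Oracle: bisection on sl_fixed_point admissibility."""
        V0 = 0.005
        lo, hi = 1e-6, 100.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if sl_fixed_point(mid, 1.0, V0, params) is not None:
                lo = mid
            else:
                hi = mid
        assert q1_threshold(V0, params) == pytest.approx(lo, abs=1e-9)

    def test_representatives_on_correct_side(self, representatives, params):
        for name, t in representatives.items():
            q1_bar = q1_threshold(t.V0, params)
            if t.regime is RegimeLabel.NL:
                assert t.q1 > q1_bar
            else:
                assert t.q1 < q1_bar


class TestQ3Threshold:
    def test_bisection_contract(self, params):
        # q1 = 2.14 (fixture C2's q1): the threshold exists inside the box
        q3_bar = q3_threshold(0.005, 2.14, params)
        assert classify_regime(2.14, q3_bar * 0.98, 0.005) is RegimeLabel.SL
        assert classify_regime(2.14, q3_bar * 1.02, 0.005) is RegimeLabel.BS

    def test_reproducible(self, params):
        a = q3_threshold(0.00275, 0.5, params)
        b = q3_threshold(0.00275, 0.5, params)
        assert a == b
        assert abs(a - q3_threshold(0.00275, 0.5 + 1e-14, params)) < 1e-6

    def test_no_threshold_inside_box_raises(self, params):
        # for V0 = 0.005 and low q1, no NL root exists anywhere in q3 <= 10
        with pytest.raises(NoRootError):
            q3_threshold(0.005, 0.151, params)

    def test_requires_q1_below_threshold(self, params):
        with pytest.raises(ValueError):
            q3_threshold(0.005, 5.0, params)

    def test_bs_samples_above_threshold_classify_bs(self, params, rng):
        V0 = 0.00275
        q1_bar = q1_threshold(V0, params)
        for _ in range(10):
            q1 = rng.uniform(0.01, q1_bar)
            q3_bar = q3_threshold(V0, q1, params)
            q3 = rng.uniform(min(q3_bar * 1.001, 10.0), 10.0)
            assert classify_regime(q1, q3, V0, params) is RegimeLabel.BS


class TestDynamicsAgreement:
    def _settle(self, y0, p, weeks=400):
        traj = simulate_state(
            np.asarray(y0, float), p, null_schedule(weeks),
            SolverOptions(rtol=1e-10, atol=1e-12, coarse_step=5000.0),
        )
        return traj.states[-1]

    def test_perturbed_ic_converges_to_algebraic_root(self, params):
        q1, q3, V0 = 0.503, 0.272, 0.0005
        fp = nl_fixed_point(q1, q3, V0, params)
        p = params.for_tumour(q1, q3)
        end = self._settle(
            [fp.T_star * 0.9, 0, 0, 0, V0, min(1.0, fp.c_star * 1.5), 0], p
        )
        assert abs(end[0] - fp.T_star) < 1e-6
        assert abs(end[5] - fp.c_star) < 1e-6

    def test_bistability_witness(self, params):
        q1, q3, V0 = 1.0, 9.0, 0.00275
        p = params.for_tumour(q1, q3)
        nl = nl_fixed_point(q1, q3, V0, params)
        sl = sl_fixed_point(q1, q3, V0, params)
        low = self._settle([0.01, 0, 0, 0, V0, 1.0, 0], p)
        high = self._settle([1.0 - V0 - 1e-4, 0, 0, 0, V0, 1.0, 0], p)
        assert abs(low[0] - nl.T_star) < 1e-6
        assert abs(high[0] - sl.T_star) < 1e-6

    def test_unstable_candidates_not_returned(self, params):
        # in the bistable box the quadratic has two roots; only one is stable
        cands = nl_candidates(1.0, 9.0, 0.00275, params)
        assert len(cands) == 2
        assert sum(fp.stable for fp in cands) == 1
        assert nl_fixed_point(1.0, 9.0, 0.00275, params).stable
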