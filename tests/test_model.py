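"""Feedback-model dynamics: numeric/analytic agreement, conservation,
derived rates, effect sizes and the mating scenario."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spermlimit.model import (
    DEFAULT_ATOL,
    DEFAULT_RTOL,
    EggLayingParams,
    analytic_state,
    analytic_trajectory,
    effect_size,
    effect_size_crossings,
    egg_rate,
    simulate_numeric,
    simulate_with_mating,
    sperm_remaining,
    window_eggs,
)

TIMES = np.array([6.0, 24.0, 48.0, 66.0, 90.0])


def rk4_oracle(params, t_end, h=1e-3):
    """Fixed-step classical RK4, independent of the adaptive solver."""
    k_o, k_f = params.k_o, params.k_f
    y = np.array([params.s_0, 0.0, 0.0])

    def f(y):
        flux = k_f * y[1] * y[0]
        return np.array([-flux, k_o - flux, flux])

    n = int(round(t_end / h))
    for _ in range(n):
        k1 = f(y)
        k2 = f(y + 0.5 * h * k1)
        k3 = f(y + 0.5 * h * k2)
        k4 = f(y + h * k3)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return y  # (S, O, E)


class TestNumericSolution:
    def test_initial_condition(self, base_params):
        traj = simulate_numeric(base_params, [0.0])
        assert (traj.S[0], traj.O[0], traj.E[0]) == (base_params.s_0, 0.0, 0.0)

    def test_decoupled_limit_oocytes_accumulate_linearly(self):
        p = EggLayingParams(k_o=5.0, k_f=1e-12, s_0=300.0)
        traj = simulate_numeric(p, [10.0])
        assert traj.S[0] == pytest.approx(300.0, abs=1e-6)
        assert traj.O[0] == pytest.approx(50.0, abs=1e-6)
        assert traj.E[0] == pytest.approx(0.0, abs=1e-6)

    def test_against_fixed_step_rk4(self, base_params):
        S, O, E = rk4_oracle(base_params, 48.0)
        traj = simulate_numeric(base_params, [48.0])
        assert traj.S[0] == pytest.approx(S, rel=1e-6)
        assert traj.O[0] == pytest.approx(O, rel=1e-6)
        assert traj.E[0] == pytest.approx(E, rel=1e-6)

    def test_rejects_bad_times(self, base_params):
        with pytest.raises(ValueError):
            simulate_numeric(base_params, [10.0, 5.0])
        with pytest.raises(ValueError):
            simulate_numeric(base_params, [-1.0, 5.0])

    def test_monotone_sperm_and_eggs(self, base_params):
        t = np.linspace(0.0, 150.0, 80)
        traj = simulate_numeric(base_params, t)
        assert np.all(np.diff(traj.S) <= 1e-9)
        assert np.all(np.diff(traj.E) >= -1e-9)
        assert np.all(traj.O >= -1e-9)


class TestAnalyticSolution:
    def test_initial_state_exact(self, grid_params):
        for p in grid_params[::7]:
            st0 = analytic_state(p, 0.0)
            assert st0.S == pytest.approx(p.s_0, rel=1e-12)
            assert st0.O == pytest.approx(0.0, abs=1e-9)
            assert st0.E == pytest.approx(0.0, abs=1e-9)

    def test_matches_numeric_at_assay_times(self, base_params):
        a = analytic_trajectory(base_params, TIMES)
        n = simulate_numeric(base_params, TIMES)
        for x, y in ((a.S, n.S), (a.O, n.O), (a.E, n.E)):
            assert np.all(np.abs(x - y) <= 1e-6 * np.maximum(np.abs(y), 1.0))

    def test_all_sperm_eventually_used(self, base_params):
        st_late = analytic_state(base_params, 1e4)
        assert st_late.E == pytest.approx(base_params.s_0, abs=1e-3)
        assert st_late.S == pytest.approx(0.0, abs=1e-3)

    def test_overflow_regime_is_finite_and_correct(self):
        # naive exp(k_f S_0^2 / 2 k_o) here is exp(1250): far beyond double range
        p = EggLayingParams(k_o=1.0, k_f=1e-2, s_0=500.0)
        a = analytic_trajectory(p, TIMES)
        n = simulate_numeric(p, TIMES)
        assert np.all(np.isfinite(a.S))
        assert np.allclose(a.S, n.S, rtol=1e-6)

    def test_negative_time_rejected(self, base_params):
        with pytest.raises(ValueError):
            analytic_state(base_params, -0.5)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        k_o=st.floats(1.0, 10.0),
        k_f=st.floats(1e-4, 1e-3),
        s_0=st.floats(100.0, 500.0),
        t=st.floats(0.0, 120.0),
    )
    def test_conservation_property(self, k_o, k_f, s_0, t):
        """E + S = S_0 and O + E = k_o t hold for any physiological state."""
        p = EggLayingParams(k_o=k_o, k_f=k_f, s_0=s_0)
        s = analytic_state(p, t)
        tol = 10.0 * (DEFAULT_RTOL * s_0 + DEFAULT_ATOL)
        assert abs(s.E + s.S - s_0) <= tol
        assert abs(s.O + s.E - k_o * t) <= tol
        assert s.S >= 0 and s.O >= 0 and s.E >= 0


class TestEggRate:
    def test_zero_at_start_no_oocytes_yet(self, base_params):
        assert egg_rate(base_params, 0.0) == 0.0

    def test_rises_then_falls_single_interior_maximum(self, base_params):
        t = np.linspace(0.0, 200.0, 4001)[1:]
        r = egg_rate(base_params, t)
        i = int(np.argmax(r))
        assert 0 < i < len(r) - 1
        d = np.diff(r)
        # one sign change in the derivative: strictly up, then strictly down
        assert np.all(d[: i - 1] > 0) and np.all(d[i + 1 :] < 0)

    def test_vanishing_fertilization_rate(self):
        p = EggLayingParams(k_o=5.0, k_f=1e-15, s_0=263.0)
        t = np.linspace(0.0, 100.0, 11)
        assert np.all(egg_rate(p, t) <= 1e-8)


class TestWindowEggs:
    def test_zero_length_window(self, base_params):
        assert window_eggs(base_params, 24.0, 24.0) == 0.0

    def test_lifetime_fecundity_equals_sperm_pool(self, base_params):
        total = window_eggs(base_params, 0.0, 1e5)
        assert total == pytest.approx(base_params.s_0, rel=1e-6)

    def test_additive_over_abutting_windows(self, base_params):
        whole = window_eggs(base_params, 18.0, 48.0)
        parts = (
            window_eggs(base_params, 18.0, 24.0)
            + window_eggs(base_params, 24.0, 42.0)
            + window_eggs(base_params, 42.0, 48.0)
        )
        assert whole == pytest.approx(parts, rel=1e-9)

    def test_matches_quadrature_of_rate(self, base_params):
        from scipy.integrate import quad

        val, _ = quad(lambda t: egg_rate(base_params, t), 18.0, 24.0, epsabs=1e-10)
        assert window_eggs(base_params, 18.0, 24.0) == pytest.approx(val, rel=1e-7)

    def test_reversed_window_rejected(self, base_params):
        with pytest.raises(ValueError):
            window_eggs(base_params, 24.0, 18.0)


class TestEffectSize:
    def test_identical_params_zero_everywhere(self, base_params):
        d = effect_size(base_params, base_params, np.linspace(0, 100, 20))
        assert np.all(d == 0.0)

    def test_oocyte_rate_difference_flips_sign_once(self, base_params):
        """A higher k_o lays faster early but exhausts sperm sooner: the
        effect-size curve crosses zero exactly once, early sign +."""
        fast = base_params.replace(k_o=7.0)
        crossings = effect_size_crossings(fast, base_params)
        assert len(crossings) == 1
        t_x = crossings[0]
        early = effect_size(fast, base_params, [0.5 * t_x])[0]
        late = effect_size(fast, base_params, [1.5 * t_x])[0]
        assert early > 0 > late

    def test_sperm_pool_difference_dominates_late(self, base_params):
        big = base_params.replace(s_0=400.0)
        t_late = 5.0 * base_params.s_0 / base_params.k_o
        assert effect_size(big, base_params, [t_late])[0] > 0
        assert effect_size(base_params, big, [t_late])[0] < 0

    def test_window_mode_matches_manual_differences(self, base_params):
        fast = base_params.replace(k_o=7.0)
        wins = [(18.0, 24.0), (60.0, 66.0)]
        d = effect_size(fast, base_params, wins, mode="window")
        manual = [
            (window_eggs(fast, a, b) - window_eggs(base_params, a, b)) / (b - a)
            for a, b in wins
        ]
        assert np.allclose(d, manual)


class TestSpermRemaining:
    def test_starts_at_pool_size_and_empties(self, base_params):
        assert sperm_remaining(base_params, 0.0) == pytest.approx(base_params.s_0)
        assert sperm_remaining(base_params, 1e5) == pytest.approx(0.0, abs=1e-3)

    def test_faster_oocyte_rate_uses_sperm_sooner(self, base_params):
        fast = base_params.replace(k_o=7.0)
        t = np.linspace(1.0, 150.0, 60)
        assert np.all(sperm_remaining(fast, t) <= sperm_remaining(base_params, t) + 1e-9)

    def test_strictly_decreasing_while_positive(self, base_params):
        t = np.linspace(0.0, 100.0, 50)
        s = sperm_remaining(base_params, t)
        assert np.all(np.diff(s) < 0)


class TestMating:
    def test_no_sperm_added_identical_to_unmated(self, base_params):
        t = np.array([6.0, 30.0, 60.0])
        a = simulate_with_mating(base_params, 24.0, 0.0, t)
        b = simulate_numeric(base_params, t)
        assert np.allclose(a.S, b.S) and np.allclose(a.E, b.E)

    def test_post_mating_conservation(self, base_params):
        t = np.array([6.0, 24.0, 30.0, 48.0, 66.0, 90.0])
        traj = simulate_with_mating(base_params, 24.0, 1000.0, t)
        post = t > 24.0
        assert np.allclose(
            traj.E[post] + traj.S[post], base_params.s_0 + 1000.0, rtol=1e-7
        )
        pre = t <= 24.0
        assert np.allclose(traj.E[pre] + traj.S[pre], base_params.s_0, rtol=1e-7)

    def test_sperm_topup_rescues_late_rate(self, base_params):
        """Adding ~1000 male sperm at 24 h keeps the late egg-laying rate
        above the unmated, self-sperm-limited trajectory."""
        t = np.array([66.0])
        m = simulate_with_mating(base_params, 24.0, 1000.0, t)
        u = simulate_numeric(base_params, t)
        rate_m = base_params.k_f * m.O[0] * m.S[0]
        rate_u = base_params.k_f * u.O[0] * u.S[0]
        assert rate_m > rate_u

    def test_invalid_arguments(self, base_params):
        with pytest.raises(ValueError):
            simulate_with_mating(base_params, -1.0, 100.0, [10.0])
        with pytest.raises(ValueError):
            simulate_with_mating(base_params, 10.0, -5.0, [20.0])


class TestParamValidation:
    @pytest.mark.parametrize("bad", [
        dict(k_o=0.0, k_f=1e-4, s_0=100.0),
        dict(k_o=5.0, k_f=-1e-4, s_0=100.0),
        dict(k_o=5.0, k_f=1e-4, s_0=float("inf")),
    ])
    def test_rejects_nonphysiological(self, bad):
        with pytest.raises(ValueError):
            EggLayingParams(**bad)
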