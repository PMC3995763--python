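"""Rate laws, forward simulation against closed forms, feasibility."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lifephases as lp
from lifephases import (
    ControlSchedule,
    check_feasibility,
    energy_rate,
    knowledge_rate,
    simulate,
    terminal_energy,
)

P = lp.ModelParams()
BC = lp.BoundaryConstraints()


class TestRateLaws:
    @pytest.mark.parametrize(
        "L,u,expected",
        [
            (0.0, 0.0, -0.02),            # zero knowledge: pure maintenance loss
            (1.0, 0.0, 0.48),             # half-saturation intake minus m
            (1e9, 1.0, 1.0 - 0.02 - 1.0), # saturation limit f_max - m - u
        ],
    )
    def test_energy_rate_examples(self, L, u, expected):
        assert energy_rate(5.0, L, u, P) == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize(
        "L,u,expected",
        [(0.0, 0.0, 0.0), (0.0, 1.0, 1.0), (1.0 * 0.7 / 0.08, 0.7, 0.0)],
    )
    def test_knowledge_rate_examples(self, L, u, expected):
        assert knowledge_rate(L, u, P) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("fn", [energy_rate, knowledge_rate])
    def test_negative_inputs_rejected(self, fn):
        args = (5.0,) if fn is energy_rate else ()
        with pytest.raises(ValueError):
            fn(*args, -0.1, 0.0, P)
        with pytest.raises(ValueError):
            fn(*args, 0.0, -0.1, P)

    @given(
        L1=st.floats(0.0, 50.0),
        dL=st.floats(1e-6, 10.0),
        u=st.floats(0.0, 1.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_energy_rate_monotone_in_knowledge_and_bounded(self, L1, dL, u):
        r1 = energy_rate(5.0, L1, u, P)
        r2 = energy_rate(5.0, L1 + dL, u, P)
        assert r2 > r1
        assert r2 <= P.f_max - P.m - u + 1e-12

    @given(L=st.floats(0.0, 50.0), u=st.floats(0.0, 0.9), du=st.floats(1e-6, 0.1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_energy_rate_strictly_decreasing_in_u(self, L, u, du):
        assert energy_rate(5.0, L, u + du, P) < energy_rate(5.0, L, u, P)


class TestControlSchedule:
    def test_linear_vs_previous_interpolation(self):
        s_lin = ControlSchedule([0.0, 1.0], [0.0, 1.0], "linear")
        s_prev = ControlSchedule([0.0, 1.0], [0.0, 1.0], "previous")
        assert s_lin(0.5) == pytest.approx(0.5)
        assert s_prev(0.5) == 0.0
        assert s_prev(1.0) == 1.0

    def test_validation(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            ControlSchedule([0.0, 0.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="interpolation"):
            ControlSchedule([0.0, 1.0], [0.0, 0.0], "cubic")

    def test_bang_switch_outside_horizon(self):
        with pytest.raises(ValueError, match="outside"):
            ControlSchedule.bang(25.0, 20.0, 1.0)


class TestSimulate:
    def test_zero_investment_matches_linear_decay(self):
        traj = simulate(P, BC, ControlSchedule.constant(0.0, P.T_max))
        expected = BC.E0 - P.m * traj.times
        assert np.max(np.abs(traj.E_values - expected)) < 1e-6
        assert np.all(traj.L_values == 0.0)
        assert terminal_energy(traj) == pytest.approx(5.1, abs=1e-9)

    @pytest.mark.parametrize("c", [0.2, 0.7])
    def test_constant_investment_matches_exponential_knowledge(self, c):
        traj = simulate(P, BC, ControlSchedule.constant(c, P.T_max))
        for t_query in (P.T_max / 2, P.T_max):
            L_exact = (P.alpha * c / P.m_L) * (1.0 - np.exp(-P.m_L * t_query))
            assert traj.L(t_query) == pytest.approx(L_exact, abs=1e-6)

    def test_knowledge_converges_monotonically_to_fixed_point(self):
        c = 0.5
        traj = simulate(P, BC, ControlSchedule.constant(c, P.T_max))
        L_star = P.alpha * c / P.m_L
        assert np.all(np.diff(traj.L_values) >= -1e-12)
        assert np.all(traj.L_values <= L_star + 1e-9)

    def test_step_halving_changes_terminal_energy_below_tolerance(self):
        sched = ControlSchedule.constant(0.3, P.T_max)
        e1 = terminal_energy(simulate(P, BC, sched, step=P.T_max / 2000))
        e2 = terminal_energy(simulate(P, BC, sched, step=P.T_max / 4000))
        assert abs(e1 - e2) < 1e-9

    def test_degenerate_horizon_returns_initial_state(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_tiny = P.replace(T_max=1e-9)
        traj = simulate(p_tiny, BC, ControlSchedule.constant(1.0, 1e-9))
        assert traj.E_values[0] == BC.E0
        assert traj.E_values[-1] == pytest.approx(BC.E0, abs=1e-8)

    def test_short_control_schedule_rejected(self):
        with pytest.raises(ValueError, match="ends at"):
            simulate(P, BC, ControlSchedule.constant(0.0, P.T_max / 2))


class TestTerminalEnergyAndFeasibility:
    def test_terminal_is_last_grid_value(self):
        traj = lp.StateTrajectory([0.0, 1.0], [5.5, 5.2], [0.0, 0.1])
        assert terminal_energy(traj) == 5.2

    def test_single_point_trajectory(self):
        traj = lp.StateTrajectory([0.0], [5.5], [0.0])
        assert terminal_energy(traj) == 5.5

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            terminal_energy(lp.StateTrajectory([], [], []))

    def test_zero_strategy_is_feasible(self):
        sched = ControlSchedule.constant(0.0, P.T_max)
        rep = check_feasibility(simulate(P, BC, sched), sched, BC, P)
        assert rep.ok
        assert rep.summary().startswith("feasible")

    def test_full_throttle_crashes_through_floor(self):
        sched = ControlSchedule.constant(1.0, P.T_max)
        rep = check_feasibility(simulate(P, BC, sched), sched, BC, P)
        assert not rep.ok
        assert rep.by_kind("E_floor")

    def test_control_above_ceiling_reported(self):
        sched = ControlSchedule.constant(0.0, P.T_max)
        bad = ControlSchedule([0.0, P.T_max], [1.5, 0.0], "previous")
        rep = check_feasibility(simulate(P, BC, sched), bad, BC, P)
        assert rep.by_kind("u_upper")


class TestViability:
    def test_baseline_singular_level_closed_form(self):
        assert lp.singular_knowledge_level(P) == pytest.approx(np.sqrt(1 / 0.08) - 1)
        assert lp.sustainable_net_rate(P) > 0

    def test_unsustainable_corner_detected(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = lp.ModelParams(f_max=10, k_L=10, alpha=0.5, m_L=1.0, T_max=100)
        assert lp.sustainable_net_rate(p) < 0
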