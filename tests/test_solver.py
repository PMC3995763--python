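"""Collocation solver: baseline structure, optimality and costate checks."""

import numpy as np
import pytest

import lifephases as lp
from lifephases.collocation import Solution
from lifephases.dynamics import simulate

from conftest import make_solution

P = lp.ModelParams()
BC = lp.BoundaryConstraints()


class TestSolverOptions:
    def test_mesh_floor(self):
        with pytest.raises(ValueError, match="mesh"):
            lp.SolverOptions(mesh=10)

    def test_positive_tolerances(self):
        with pytest.raises(ValueError):
            lp.SolverOptions(nlp_tol=0.0)


class TestBaselineSolution:
    def test_objective_equals_terminal_energy(self, baseline_results):
        sol = baseline_results.solution
        assert sol.objective == pytest.approx(
            lp.terminal_energy(sol.states), abs=1e-6
        )

    def test_feasible_at_tolerance(self, baseline_results):
        assert baseline_results.solution.feasibility(tol=1e-4).ok

    def test_starts_at_full_investment(self, baseline_results):
        u0 = float(baseline_results.control(0.0))
        assert u0 == pytest.approx(BC.control_ceiling(P), abs=1e-3)

    def test_ends_with_zero_investment(self, baseline_results):
        T = P.T_max
        assert float(baseline_results.control(T)) <= 1e-6

    def test_dominates_heuristic_suite(self, baseline_results):
        d = baseline_results.diagnostics
        assert baseline_results.objective >= d["heuristic_best"] - 1e-3

    def test_mesh_refinement_converged(self, baseline_results):
        d = baseline_results.diagnostics
        assert d["mesh_converged"]
        hist = d["objective_history"]
        assert abs(hist[-1] - hist[-2]) < 1e-4

    def test_floor_active_on_single_contiguous_interval(self, baseline_results):
        E = baseline_results.states.E_values
        active = E <= BC.E_min + 1e-6
        idx = np.flatnonzero(active)
        assert idx.size > 0
        assert np.all(np.diff(idx) == 1)  # one contiguous interval
        assert np.all(E[idx[-1] + 1 :] > BC.E_min)

    def test_maintenance_holds_singular_knowledge_level(self, baseline_results):
        """The held knowledge level matches the closed-form singular level
        sqrt(alpha*f_max*k_L/m_L) - k_L."""
        seg = baseline_results.phases()
        span = seg.segment_for("maintenance")
        assert span is not None
        t = baseline_results.states.times
        mask = (t >= span[0] + 0.5) & (t <= span[1] - 0.5)
        L_held = baseline_results.states.L_values[mask]
        assert np.ptp(L_held) < 0.02
        assert np.mean(L_held) == pytest.approx(lp.singular_knowledge_level(P), rel=0.02)


class TestMeshAndMultistart:
    def test_doubling_mesh_barely_moves_objective(self):
        o1 = lp.solve_ocp(P, BC, lp.SolverOptions(mesh=60, refinement_rounds=0))
        o2 = lp.solve_ocp(P, BC, lp.SolverOptions(mesh=120, refinement_rounds=0))
        assert abs(o1.objective - o2.objective) < 1e-4

    def test_multistart_seeds_agree(self):
        objs = [
            lp.solve_ocp(
                P, BC, lp.SolverOptions(mesh=40, refinement_rounds=0, seed=s)
            ).objective
            for s in range(5)
        ]
        assert max(objs) - min(objs) < 1e-3

    def test_infeasible_problem_reports_explicit_failure(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_dead = lp.ModelParams(f_max=10, k_L=10, alpha=0.5, m_L=1.0, T_max=100)
        sol = lp.solve_ocp(p_dead, BC, lp.SolverOptions(mesh=24, refinement_rounds=0, n_multistart=2))
        assert not sol.converged
        assert sol.diagnostics["status"] == "nlp_failed"


class TestCostates:
    def test_terminal_conditions(self, baseline_results):
        cs = baseline_results.costates
        assert cs["lambda_E"][-1] == pytest.approx(1.0, abs=1e-9)
        assert cs["lambda_L"][-1] == pytest.approx(0.0, abs=1e-9)

    def test_energy_costate_constant_on_final_arc(self, baseline_results):
        seg = baseline_results.phases()
        t0, _ = seg.segment_for("exploitation")
        t = baseline_results.states.times
        lam_E = baseline_results.costates["lambda_E"]
        assert np.max(np.abs(lam_E[t >= t0] - 1.0)) < 1e-9

    def test_knowledge_costate_positive_before_terminal(self, baseline_results):
        seg = baseline_results.phases()
        t0, t1 = seg.segment_for("exploitation")
        t = baseline_results.states.times
        mask = (t >= t0) & (t < t1 - 1e-9)
        assert np.all(baseline_results.costates["lambda_L"][mask] > 0.0)

    def test_switching_function_terminal_value(self, baseline_results):
        assert baseline_results.switching(P.T_max) == pytest.approx(-1.0, abs=1e-9)

    def test_switching_positive_on_establishment(self, baseline_results):
        assert baseline_results.switching(0.0) > -0.01

    def test_switching_vanishes_on_maintenance(self, baseline_results):
        span = baseline_results.phases().segment_for("maintenance")
        mid = 0.5 * (span[0] + span[1])
        assert abs(baseline_results.switching(mid)) < 0.02

    def test_floor_multiplier_nonnegative(self, baseline_results):
        # up to a junction boundary-layer artefact where L marginally
        # overshoots the singular level at the arc exit
        assert np.min(baseline_results.costates["eta"]) >= -1e-3

    def test_query_outside_horizon_rejected(self, baseline_results):
        with pytest.raises(ValueError, match="outside"):
            baseline_results.switching(P.T_max + 1.0)

    def test_costates_require_feasible_solution(self):
        t = np.linspace(0, 20, 50)
        bad = make_solution(P, BC, t, np.full_like(t, 4.5), np.zeros_like(t), np.zeros_like(t))
        with pytest.raises(ValueError, match="infeasible"):
            lp.estimate_costates(bad, P)


class TestPMPCheck:
    def test_optimal_solution_consistent(self, baseline_results):
        rep = baseline_results.pmp_report()
        assert rep["pass"]
        assert rep["fraction_consistent"] >= 0.95

    def test_perturbed_final_arc_fails(self, baseline_results):
        sol = baseline_results.solution
        t = sol.states.times
        seg = baseline_results.phases()
        t3 = seg.segments[-1][1]
        i3 = int(np.searchsorted(t, t3))
        # re-simulate the tail under u*+0.3, splice onto the optimal head
        p_tail = P.replace(T_max=P.T_max - t[i3])
        bc_tail = BC.replace(E0=sol.states.E_values[i3], L0=sol.states.L_values[i3])
        u_tail = np.clip(np.asarray(sol.control(t[i3:])) + 0.3, 0, 1)
        tail = simulate(
            p_tail, bc_tail, lp.ControlSchedule(t[i3:] - t[i3], u_tail, "linear")
        )
        E2 = np.concatenate(
            [sol.states.E_values[:i3], np.interp(t[i3:] - t[i3], tail.times, tail.E_values)]
        )
        L2 = np.concatenate(
            [sol.states.L_values[:i3], np.interp(t[i3:] - t[i3], tail.times, tail.L_values)]
        )
        u2 = np.concatenate([np.asarray(sol.control(t[:i3])), u_tail])
        sol2 = make_solution(P, BC, t, E2, L2, u2)
        lp.estimate_costates(sol2, P)
        assert not lp.check_pmp(sol2)["pass"]

    def test_zero_strategy_fails_establishment_detection(self):
        t = np.linspace(0.0, 20.0, 401)
        traj = simulate(P, BC, lp.ControlSchedule.constant(0.0, 20.0))
        sol = make_solution(P, BC, t, np.interp(t, traj.times, traj.E_values),
                            np.zeros_like(t), np.zeros_like(t))
        lp.estimate_costates(sol, P)
        assert not lp.check_pmp(sol)["pass"]

    def test_costates_required(self):
        t = np.linspace(0.0, 20.0, 50)
        sol = make_solution(P, BC, t, 5.5 - 0.02 * t, np.zeros_like(t), np.zeros_like(t))
        with pytest.raises(ValueError, match="costates"):
            lp.check_pmp(sol)


class TestResultsSurface:
    def test_summary_mentions_phases_and_objective(self, baseline_results):
        s = baseline_results.summary()
        assert "terminal energy" in s
        assert "establishment" in s and "exploitation" in s

    def test_frame_has_costate_columns(self, baseline_results):
        df = baseline_results.to_frame()
        assert list(df.columns) == ["time", "E", "L", "u", "lambda_E", "lambda_L", "sigma"]
        assert len(df) == len(baseline_results.states)

    def test_csv_round_trip(self, baseline_results, tmp_path):
        import pandas as pd

        path = tmp_path / "sol.csv"
        baseline_results.to_csv(path)
        df = pd.read_csv(path)
        np.testing.assert_allclose(df["E"], baseline_results.states.E_values, rtol=1e-12)

    def test_plot_writes_file(self, baseline_results, tmp_path):
        out = tmp_path / "fig.png"
        baseline_results.plot(out)
        assert out.stat().st_size > 0
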