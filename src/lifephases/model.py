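"""Model/Results surface tying the solver, oracle and classifier together.

Usage follows the familiar model-object idiom::

    model = LifetimeExplorationModel()            # baseline parameters
    res = model.fit()                             # solve for u*(t)
    print(res.summary())
    res.phases()                                  # PhaseSegmentation
    res.to_frame()                                # tidy trajectory table
    res.plot("figure.png")                        # states + control panels

The model object is the problem statement (parameters, boundary values);
the results object carries the optimal trajectory, costates, phase
segmentation, diagnostics and exports.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from .collocation import SolverOptions, Solution, heuristic_suite, solve_ocp
from .dp import DPResult, GridSpec, compare_with_ocp, dp_solve
from .dynamics import ControlSchedule, StateTrajectory, check_feasibility, simulate
from .params import BoundaryConstraints, ModelParams
from .phases import PhaseSegmentation, PhaseTolerances, classify_phases, phase_fractions
from .pmp import check_pmp, switching_function

__all__ = ["LifetimeExplorationModel", "OptimalControlResults"]


class LifetimeExplorationModel:
    """The lifetime exploration-exploitation control problem.

    Parameters default to the worked baseline (f_max=1, k_L=1, m=0.02,
    alpha=1, m_L=0.08, T_max=20; E0=5.5, E_min=5, u in [0, 1]).
    """

    def __init__(
        self,
        params: ModelParams | None = None,
        constraints: BoundaryConstraints | None = None,
    ):
        self.params = params if params is not None else ModelParams()
        self.constraints = constraints if constraints is not None else BoundaryConstraints()

    @classmethod
    def from_dict(cls, mapping: dict) -> "LifetimeExplorationModel":
        """Build from a flat mapping of Table-style names (f_max ... u_max)."""
        pkeys = ModelParams().to_dict().keys()
        bkeys = BoundaryConstraints().to_dict().keys()
        unknown = set(mapping) - set(pkeys) - set(bkeys)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        p = ModelParams(**{k: v for k, v in mapping.items() if k in pkeys})
        bc = BoundaryConstraints(**{k: v for k, v in mapping.items() if k in bkeys})
        return cls(p, bc)

    @property
    def control_ceiling(self) -> float:
        return self.constraints.control_ceiling(self.params)

    def simulate(self, control: ControlSchedule, step: float | None = None) -> StateTrajectory:
        """Forward-simulate a given strategy (no constraint enforcement)."""
        return simulate(self.params, self.constraints, control, step=step)

    def feasibility(self, traj: StateTrajectory, control: ControlSchedule, tol: float = 1e-6):
        return check_feasibility(traj, control, self.constraints, self.params, tol=tol)

    def heuristics(self) -> dict:
        return heuristic_suite(self.params, self.constraints)

    def fit(self, options: SolverOptions | None = None) -> "OptimalControlResults":
        """Solve for the optimal strategy u*(t)."""
        sol = solve_ocp(self.params, self.constraints, options)
        return OptimalControlResults(self, sol)

    # alias for callers thinking in optimal-control terms
    solve = fit

    def dp_solve(self, grid: GridSpec | None = None) -> DPResult:
        """Run the brute-force dynamic-programming oracle."""
        return dp_solve(self.params, self.constraints, grid)


class OptimalControlResults:
    """A solved lifetime strategy with uncertainty-free diagnostics.

    Wraps the raw :class:`~lifephases.collocation.Solution`; adds phase
    segmentation, the first-order consistency report, tidy exports and a
    text summary.
    """

    def __init__(self, model: LifetimeExplorationModel, solution: Solution):
        self.model = model
        self.solution = solution
        self._segmentation: PhaseSegmentation | None = None

    # -- pass-throughs
    @property
    def params(self) -> ModelParams:
        return self.solution.params

    @property
    def constraints(self) -> BoundaryConstraints:
        return self.solution.constraints

    @property
    def objective(self) -> float:
        return self.solution.objective

    @property
    def converged(self) -> bool:
        return self.solution.converged

    @property
    def control(self) -> ControlSchedule:
        return self.solution.control

    @property
    def states(self) -> StateTrajectory:
        return self.solution.states

    @property
    def costates(self) -> dict:
        return self.solution.costates

    @property
    def diagnostics(self) -> dict:
        return self.solution.diagnostics

    def phases(self, tolerances: PhaseTolerances | None = None) -> PhaseSegmentation:
        if self._segmentation is None or tolerances is not None:
            seg = classify_phases(self.solution, self.constraints, tolerances)
            if tolerances is not None:
                return seg
            self._segmentation = seg
        return self._segmentation

    def phase_fractions(self) -> dict[str, float]:
        return phase_fractions(self.phases(), self.params.T_max)

    def switching(self, t):
        return switching_function(self.solution, t)

    def pmp_report(self, **kw) -> dict:
        return check_pmp(self.solution, **kw)

    def dp_check(self, grid: GridSpec | None = None) -> dict:
        """Cross-validate the objective against the DP oracle."""
        dp = dp_solve(self.params, self.constraints, grid)
        return compare_with_ocp(self.solution, dp)

    # -- exports
    def to_frame(self) -> pd.DataFrame:
        t = self.states.times
        cols = {
            "time": t,
            "E": self.states.E_values,
            "L": self.states.L_values,
            "u": np.asarray(self.control(t), dtype=float),
        }
        if self.costates:
            cols["lambda_E"] = self.costates["lambda_E"]
            cols["lambda_L"] = self.costates["lambda_L"]
            cols["sigma"] = self.costates["sigma"]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.15g")

    def sidecar(self) -> dict:
        """JSON-serialisable provenance record for one solve."""
        d = dict(self.diagnostics)
        d.pop("heuristic_entries", None)
        return {
            "objective": self.objective,
            "params": self.params.to_dict(),
            "constraints": self.constraints.to_dict(),
            "options": asdict(self.solution.options),
            "diagnostics": _jsonable(d),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.sidecar(), fh, indent=2, sort_keys=True)

    def plot(self, path=None):
        """Two stacked panels: states E and L, and the strategy u*(t),
        with phase boundaries as dashed verticals."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        t = self.states.times
        fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(7, 6))
        ax1.plot(t, self.states.E_values, "b-", label="energy E")
        ax1.plot(t, self.states.L_values, "g--", label="knowledge L")
        ax1.set_ylabel("state")
        ax1.legend(loc="best")
        ax2.plot(t, np.asarray(self.control(t)), "r-", label="u*(t)")
        ax2.set_xlabel("time")
        ax2.set_ylabel("learning investment")
        try:
            seg = self.phases()
            for _, t0, _t1 in seg.segments[1:]:
                for ax in (ax1, ax2):
                    ax.axvline(t0, color="k", ls=":", lw=0.8)
        except ValueError:
            pass
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig

    def summary(self) -> str:
        p, bc = self.params, self.constraints
        lines = []
        add = lines.append
        add("Lifetime exploration-exploitation: optimal strategy")
        add("=" * 56)
        add(f"{'f_max':>8} {p.f_max:10.4g}   {'k_L':>8} {p.k_L:10.4g}   {'m':>6} {p.m:8.4g}")
        add(f"{'alpha':>8} {p.alpha:10.4g}   {'m_L':>8} {p.m_L:10.4g}   {'T_max':>6} {p.T_max:8.4g}")
        add(f"{'E0':>8} {bc.E0:10.4g}   {'E_min':>8} {bc.E_min:10.4g}   {'u_max':>6} {bc.u_max:8.4g}")
        add("-" * 56)
        add(f"converged: {self.converged}   mesh: {self.diagnostics.get('mesh')}   "
            f"refinements: {self.diagnostics.get('refinement_rounds_used')}")
        add(f"terminal energy E(T_max): {self.objective:.6f}")
        add(f"min E(t): {float(np.min(self.states.E_values)):.6f}  "
            f"(floor {bc.E_min:g})")
        add(f"max L(t): {float(np.max(self.states.L_values)):.6f}")
        if self.converged:
            try:
                seg = self.phases()
                fr = self.phase_fractions()
                add("-" * 56)
                add("knowledge phases (label, interval, fraction of life):")
                for lbl, t0, t1 in seg.segments:
                    add(f"  {lbl:<14} [{t0:7.3f}, {t1:7.3f}]   {fr[lbl]:.3f}")
            except ValueError as exc:
                add(f"phase classification unavailable: {exc}")
        return "\n".join(lines)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
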