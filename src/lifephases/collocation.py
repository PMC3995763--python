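"""Direct-collocation solver for the terminal-energy control problem.

The continuous problem

    maximise  E(T_max)
    s.t.      dE/dt = f_max*L/(L+k_L) - m - u,   E(0) = E0
              dL/dt = alpha*u - m_L*L,           L(0) = L0
              E(t) >= E_min,  L(t) >= L_min,  u(t) in [u_min, min(u_max, f_max)]

is transcribed by Hermite-Simpson collocation on a power-law-graded mesh
(denser at early times, where the establishment/accumulation transient
lives): states and control live at mesh nodes, the control is piecewise
linear, and each mesh interval contributes one Simpson defect per state
using the Hermite midpoint.  The survival floor is imposed at every node and at every Hermite
midpoint.  The resulting sparse NLP (analytic Jacobians throughout) is
solved with SLSQP, with a seeded multistart over smoothly perturbed initial
guesses and successive mesh-doubling refinement until the objective
stabilises.

The expected optimal structure is bang / state-constrained / singular /
bang: full investment while reserves allow, learning pinned to the survival
floor, a knowledge-holding singular arc, and a final zero-investment arc.
The transcription does not assume that structure; it is recovered and then
verified against first-order (Pontryagin) conditions elsewhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
from scipy.optimize import minimize

from .dynamics import (
    ControlSchedule,
    StateTrajectory,
    check_feasibility,
    simulate,
    terminal_energy,
)
from .params import BoundaryConstraints, ModelParams

__all__ = ["SolverOptions", "Solution", "solve_ocp", "heuristic_suite"]


@dataclass(frozen=True)
class SolverOptions:
    """Tuning knobs for the collocation NLP.

    mesh : int
        Number of mesh intervals of the first refinement round (>= 20).
    mesh_grading : float
        Power-law grading of the mesh: node k sits at T_max*(k/N)**grading.
        Values > 1 concentrate nodes at early times, where the
        establishment/accumulation transient lives regardless of lifetime
        (its duration is set by the reserves and rate constants, not by
        T_max); 1 recovers a uniform mesh.
    polish : bool
        Run the arc-structure polish (switching-time optimization) after
        each NLP round; removes the switch-quantization error of the
        uniform mesh.  The polished answer is kept only when it
        re-simulates at least as well as the raw mesh solution.
    refinement_rounds : int
        Maximum mesh doublings after the first solve.
    mesh_tol : float
        Objective change between rounds below which the mesh is declared
        converged.
    nlp_tol : float
        SLSQP ftol (on the scaled objective).
    maxiter : int
        SLSQP iteration cap per solve.
    n_multistart : int
        Number of initial guesses (first is the nominal ramp guess).
    seed : int
        Seed for the multistart perturbations.
    control_smoothing : float
        Weight of a quadratic penalty on control slope, damping mesh-scale
        chattering on singular arcs; 0 disables.  The reported objective is
        always the unpenalised terminal energy.
    """

    mesh: int = 60
    mesh_grading: float = 2.0
    refinement_rounds: int = 1
    mesh_tol: float = 1e-4
    nlp_tol: float = 1e-12
    maxiter: int = 600
    n_multistart: int = 3
    seed: int = 0
    control_smoothing: float = 0.0
    polish: bool = True

    def __post_init__(self) -> None:
        if self.mesh < 20:
            raise ValueError("mesh must be >= 20 intervals")
        if self.nlp_tol <= 0 or self.mesh_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.refinement_rounds < 0 or self.n_multistart < 1:
            raise ValueError("refinement_rounds >= 0 and n_multistart >= 1 required")
        if self.mesh_grading < 1.0:
            raise ValueError("mesh_grading must be >= 1")

    def replace(self, **changes) -> "SolverOptions":
        return _dc_replace(self, **changes)


@dataclass
class Solution:
    """One solved optimal-control problem.

    ``objective`` is the terminal energy of ``states`` (they agree by
    construction).  ``costates`` maps ``lambda_E``/``lambda_L`` to arrays on
    the same mesh once :func:`lifephases.pmp.estimate_costates` has run
    (solve_ocp runs it automatically on convergence).
    """

    params: ModelParams
    constraints: BoundaryConstraints
    options: SolverOptions
    control: ControlSchedule
    states: StateTrajectory
    objective: float
    costates: dict[str, np.ndarray] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))

    @property
    def times(self) -> np.ndarray:
        return self.states.times

    def feasibility(self, tol: float = 1e-4):
        return check_feasibility(
            self.states, self.control, self.constraints, self.params, tol=tol
        )


# ---------------------------------------------------------------------------
# NLP assembly


class _Transcription:
    """Hermite-Simpson NLP for a fixed mesh.

    Variable layout: [E, L, u], each nondimensionalised by a problem-scale
    (sE ~ maximal attainable energy, sL ~ the knowledge fixed point, su =
    the control ceiling) so that SLSQP sees O(1) variables and constraints
    across the whole published parameter box.
    """

    def __init__(self, p: ModelParams, bc: BoundaryConstraints, N: int, reg: float,
                 grading: float = 1.0):
        self.p, self.bc, self.N = p, bc, N
        self.n = N + 1
        self.reg = reg
        self.ceiling = bc.control_ceiling(p)
        self.sE = max(1.0, bc.E0 + (p.f_max - p.m) * p.T_max)
        self.sL = max(1.0, p.alpha * self.ceiling / p.m_L)
        self.su = self.ceiling
        self.scale = self.sE
        self.times = p.T_max * np.linspace(0.0, 1.0, self.n) ** grading
        self.h = np.diff(self.times)          # per-interval steps (N,)

    # -- unpacking helpers (return PHYSICAL quantities)
    def split(self, z):
        n = self.n
        return z[:n] * self.sE, z[n : 2 * n] * self.sL, z[2 * n :] * self.su

    def pack(self, E, L, u):
        return np.concatenate([E / self.sE, L / self.sL, u / self.su])

    def _fE(self, L, u):
        p = self.p
        return p.f_max * L / (L + p.k_L) - p.m - u

    def _fL(self, L, u):
        p = self.p
        return p.alpha * u - p.m_L * L

    def _a(self, L):
        # dfE/dL
        p = self.p
        return p.f_max * p.k_L / (L + p.k_L) ** 2

    def _mid(self, E, L, u):
        h = self.h  # (N,) per-interval
        fE0, fE1 = self._fE(L[:-1], u[:-1]), self._fE(L[1:], u[1:])
        fL0, fL1 = self._fL(L[:-1], u[:-1]), self._fL(L[1:], u[1:])
        Em = 0.5 * (E[:-1] + E[1:]) + (h / 8.0) * (fE0 - fE1)
        Lm = 0.5 * (L[:-1] + L[1:]) + (h / 8.0) * (fL0 - fL1)
        um = 0.5 * (u[:-1] + u[1:])
        return Em, Lm, um, fE0, fE1, fL0, fL1

    # -- objective (scaled: -E_N/sE plus optional control-slope penalty)
    def objective(self, z):
        E, L, u = self.split(z)
        val = -E[-1]
        if self.reg:
            val += self.reg * np.sum(np.diff(u) ** 2 / self.h)
        return val / self.sE

    def objective_grad(self, z):
        E, L, u = self.split(z)
        g = np.zeros_like(z)
        g[self.n - 1] = -self.sE
        if self.reg:
            du = np.diff(u)
            gu = np.zeros(self.n)
            gu[:-1] -= 2.0 * self.reg * du / self.h
            gu[1:] += 2.0 * self.reg * du / self.h
            g[2 * self.n :] = gu * self.su
        return g / self.sE

    # -- defects (equality constraints), 2N of them
    def defects(self, z):
        E, L, u = self.split(z)
        h = self.h
        Em, Lm, um, fE0, fE1, fL0, fL1 = self._mid(E, L, u)
        fEm = self._fE(Lm, um)
        fLm = self._fL(Lm, um)
        cE = E[1:] - E[:-1] - (h / 6.0) * (fE0 + 4.0 * fEm + fE1)
        cL = L[1:] - L[:-1] - (h / 6.0) * (fL0 + 4.0 * fLm + fL1)
        return np.concatenate([cE / self.sE, cL / self.sL])

    def defects_jac(self, z):
        E, L, u = self.split(z)
        N, n, h = self.N, self.n, self.h
        p = self.p
        Em, Lm, um, fE0, fE1, fL0, fL1 = self._mid(E, L, u)
        a0, a1, am = self._a(L[:-1]), self._a(L[1:]), self._a(Lm)
        mL, al = p.m_L, p.alpha
        hm = h * mL

        J = np.zeros((2 * N, 3 * n))
        rows = np.arange(N)

        # dLm/d(.)
        dLm_dL0 = 0.5 - hm / 8.0
        dLm_dL1 = 0.5 + hm / 8.0
        dLm_du0 = (h / 8.0) * al
        dLm_du1 = -(h / 8.0) * al

        # -- energy defects (rows 0..N-1)
        J[rows, rows] = -1.0
        J[rows, rows + 1] = 1.0
        J[rows, n + rows] = -(h / 6.0) * (a0 + 4.0 * am * dLm_dL0)
        J[rows, n + rows + 1] = -(h / 6.0) * (a1 + 4.0 * am * dLm_dL1)
        J[rows, 2 * n + rows] = -(h / 6.0) * (-3.0 + 4.0 * am * dLm_du0)
        J[rows, 2 * n + rows + 1] = -(h / 6.0) * (-3.0 + 4.0 * am * dLm_du1)

        # -- knowledge defects (rows N..2N-1)
        r2 = N + rows
        J[r2, n + rows] = -1.0 - (h / 6.0) * (-mL) * (1.0 + 4.0 * dLm_dL0)
        J[r2, n + rows + 1] = 1.0 - (h / 6.0) * (-mL) * (1.0 + 4.0 * dLm_dL1)
        J[r2, 2 * n + rows] = -(h / 6.0) * (3.0 * al + 4.0 * (-mL) * dLm_du0)
        J[r2, 2 * n + rows + 1] = -(h / 6.0) * (3.0 * al + 4.0 * (-mL) * dLm_du1)
        self._scale_jac(J, row_split=N)
        return J

    def _scale_jac(self, J, row_split):
        """Row-scale by the constraint scales, column-scale by the variable
        scales (physical Jacobian -> scaled-variable Jacobian)."""
        n = self.n
        J[:row_split, :] /= self.sE
        J[row_split:, :] /= self.sL
        J[:, :n] *= self.sE
        J[:, n : 2 * n] *= self.sL
        J[:, 2 * n :] *= self.su

    # -- midpoint survival floor (inequality >= 0), N of them
    def floor_mid(self, z):
        E, L, u = self.split(z)
        Em, *_ = self._mid(E, L, u)
        return (Em - self.bc.E_min) / self.sE

    def floor_mid_jac(self, z):
        E, L, u = self.split(z)
        N, n, h = self.N, self.n, self.h
        a0, a1 = self._a(L[:-1]), self._a(L[1:])
        J = np.zeros((N, 3 * n))
        rows = np.arange(N)
        J[rows, rows] = 0.5
        J[rows, rows + 1] = 0.5
        J[rows, n + rows] = (h / 8.0) * a0
        J[rows, n + rows + 1] = -(h / 8.0) * a1
        J[rows, 2 * n + rows] = -h / 8.0
        J[rows, 2 * n + rows + 1] = h / 8.0
        self._scale_jac(J, row_split=N)
        return J

    def bounds(self):
        bc = self.bc
        big = (bc.E0 + self.p.f_max * self.p.T_max + 10.0) / self.sE
        bE = [(bc.E_min / self.sE, big)] * self.n
        bL = [(bc.L_min / self.sL, None)] * self.n
        bu = [(bc.u_min / self.su, self.ceiling / self.su)] * self.n
        bE[0] = (bc.E0 / self.sE, bc.E0 / self.sE)
        bL[0] = (bc.L0 / self.sL, bc.L0 / self.sL)
        return bE + bL + bu

    def pack_guess(self, u_guess):
        """States from a coarse forward simulation of the guessed control,
        clipped into bounds."""
        u = np.clip(u_guess, self.bc.u_min, self.ceiling)
        sched = ControlSchedule(self.times, u)
        traj = simulate(self.p, self.bc, sched, step=self.p.T_max / (4.0 * self.N))
        E = np.interp(self.times, traj.times, traj.E_values)
        L = np.interp(self.times, traj.times, traj.L_values)
        E = np.clip(E, self.bc.E_min, None)
        L = np.clip(L, self.bc.L_min, None)
        E[0], L[0] = self.bc.E0, self.bc.L0
        return self.pack(E, L, u)


def _nominal_guess(trans: _Transcription) -> np.ndarray:
    """Linear ramp from the ceiling down to zero."""
    tau = trans.times / trans.p.T_max
    return trans.ceiling * (1.0 - tau)


def _perturbed_guess(trans: _Transcription, rng: np.random.Generator) -> np.ndarray:
    tau = trans.times / trans.p.T_max
    base = _nominal_guess(trans)
    noise = np.zeros_like(tau)
    for k in range(1, 4):
        noise += rng.normal(0.0, 1.0) * np.sin(math.pi * k * tau)
    return base + 0.2 * trans.ceiling * noise


def _solve_once(trans: _Transcription, z0, opts: SolverOptions):
    cons = [
        {"type": "eq", "fun": trans.defects, "jac": trans.defects_jac},
        {"type": "ineq", "fun": trans.floor_mid, "jac": trans.floor_mid_jac},
    ]
    res = minimize(
        trans.objective,
        z0,
        jac=trans.objective_grad,
        bounds=trans.bounds(),
        constraints=cons,
        method="SLSQP",
        options={"maxiter": opts.maxiter, "ftol": opts.nlp_tol},
    )
    max_defect = float(np.max(np.abs(trans.defects(res.x)))) if res.x is not None else np.inf
    ok = bool(res.success) and max_defect < 1e-6
    return res, ok, max_defect


def heuristic_suite(
    p: ModelParams, bc: BoundaryConstraints, n_switch: int = 20
) -> dict:
    """Best terminal energy over a fixed menu of simple feasible strategies.

    Menu: u = 0 throughout; u = ceiling throughout; and single-switch
    bang-bang (ceiling then 0) over ``n_switch`` evenly spaced switch times.
    Infeasible entries (survival-floor breach) are excluded.
    """
    ceiling = bc.control_ceiling(p)
    entries = [("constant:0", ControlSchedule.constant(0.0, p.T_max))]
    entries.append((f"constant:{ceiling:g}", ControlSchedule.constant(ceiling, p.T_max)))
    for ts in np.linspace(0.0, p.T_max, n_switch + 2)[1:-1]:
        entries.append((f"bang:{ts:g}", ControlSchedule.bang(ts, p.T_max, ceiling)))
    best, best_name, evaluated = -np.inf, None, []
    for name, sched in entries:
        traj = simulate(p, bc, sched)
        rep = check_feasibility(traj, sched, bc, p, tol=1e-6)
        obj = terminal_energy(traj) if rep.ok else -np.inf
        evaluated.append({"name": name, "objective": obj, "feasible": rep.ok})
        if obj > best:
            best, best_name = obj, name
    return {"best": best, "best_name": best_name, "entries": evaluated}


def solve_ocp(
    p: ModelParams, bc: BoundaryConstraints, opts: SolverOptions | None = None
) -> Solution:
    """Solve for the optimal lifetime learning strategy u*(t).

    Runs a seeded multistart at the base mesh, then mesh-doubling
    refinement warm-started from the incumbent, stopping when the objective
    moves by less than ``opts.mesh_tol``.  On convergence the costates are
    estimated and attached.  Non-convergence never raises: the returned
    Solution carries ``converged=False`` plus diagnostics (callers such as
    sweeps record the failure and move on).
    """
    if opts is None:
        opts = SolverOptions()
    rng = np.random.default_rng(opts.seed)

    N = opts.mesh
    trans = _Transcription(p, bc, N, opts.control_smoothing, opts.mesh_grading)
    best = None
    n_tried = 0
    for k in range(opts.n_multistart):
        u0 = _nominal_guess(trans) if k == 0 else _perturbed_guess(trans, rng)
        z0 = trans.pack_guess(u0)
        res, ok, max_defect = _solve_once(trans, z0, opts)
        n_tried += 1
        if ok and (best is None or res.fun < best[0].fun):
            best = (res, max_defect)
        if best is not None and k == 0:
            break  # nominal guess converged; multistart kept for rescue only

    def _round_result(trans_, res_):
        """Polish one NLP round; fall back to the raw mesh solution when the
        polish fails its acceptance guard."""
        E_, L_, u_ = trans_.split(res_.x)
        u_ = np.clip(u_, bc.u_min, trans_.ceiling)
        nlp_obj = float(E_[-1])
        pol = None
        if opts.polish:
            from .refine import extract_arcs, polish_arcs

            arcs, junc = extract_arcs(trans_.times, E_, u_, p, bc)
            pol = polish_arcs(p, bc, arcs, junc)
            if pol is not None:
                guard = 1e-3 * max(1.0, abs(pol.objective))
                if pol.min_E < bc.E_min - 1e-6 or pol.objective + guard < nlp_obj:
                    pol = None
        return (pol.objective if pol is not None else nlp_obj), pol

    history = []
    rounds_used = 0
    mesh_converged = False
    polished = None
    if best is not None:
        obj0, polished = _round_result(trans, best[0])
        history.append(obj0)
        for _ in range(opts.refinement_rounds):
            N2 = 2 * N
            trans2 = _Transcription(p, bc, N2, opts.control_smoothing, opts.mesh_grading)
            E, L, u = trans.split(best[0].x)
            z0 = trans2.pack(
                np.interp(trans2.times, trans.times, E),
                np.interp(trans2.times, trans.times, L),
                np.interp(trans2.times, trans.times, u),
            )
            res2, ok2, max_defect2 = _solve_once(trans2, z0, opts)
            if not ok2:
                break
            rounds_used += 1
            N, trans, best = N2, trans2, (res2, max_defect2)
            obj_r, pol_r = _round_result(trans, res2)
            if pol_r is not None or not opts.polish:
                polished = pol_r
            history.append(obj_r)
            if abs(history[-1] - history[-2]) < opts.mesh_tol:
                mesh_converged = True
                break
        if opts.refinement_rounds == 0:
            mesh_converged = True

    if best is None:
        # explicit failure: echo the problem and the diagnostics
        empty = StateTrajectory(np.array([0.0]), np.array([bc.E0]), np.array([bc.L0]))
        ctrl = ControlSchedule(np.array([0.0, p.T_max]), np.zeros(2))
        return Solution(
            p, bc, opts, ctrl, empty, -np.inf,
            diagnostics={
                "converged": False,
                "status": "nlp_failed",
                "message": "SLSQP failed to converge from all initial guesses",
                "multistarts_tried": n_tried,
                "mesh": N,
            },
        )

    res, max_defect = best
    if polished is not None:
        states = StateTrajectory(polished.times, polished.E, polished.L)
        control = ControlSchedule(
            polished.times, np.clip(polished.u, bc.u_min, trans.ceiling), "linear"
        )
    else:
        E, L, u = trans.split(res.x)
        # snap solver-noise-level bound violations on the control
        u = np.clip(u, bc.u_min, trans.ceiling)
        states = StateTrajectory(trans.times.copy(), E, L)
        control = ControlSchedule(trans.times.copy(), u, "linear")
    objective = terminal_energy(states)
    heur = heuristic_suite(p, bc)
    sol = Solution(
        p, bc, opts, control, states, objective,
        diagnostics={
            "converged": True,
            "status": "ok",
            "message": res.message,
            "mesh": N,
            "refinement_rounds_used": rounds_used,
            "mesh_converged": mesh_converged,
            "objective_history": history,
            "max_defect": max_defect,
            "nlp_iterations": int(res.nit),
            "multistarts_tried": n_tried,
            "polish_accepted": polished is not None,
            "arc_sequence": list(polished.arcs) if polished is not None else None,
            "arc_junctions": polished.junctions.tolist() if polished is not None else None,
            "heuristic_best": heur["best"],
            "heuristic_best_name": heur["best_name"],
            "max_floor_violation": float(
                max(0.0, bc.E_min - float(np.min(states.E_values)))
            ),
        },
    )
    try:
        from .pmp import estimate_costates

        estimate_costates(sol, p)
    except Exception as exc:  # costates are diagnostics; never block the solve
        sol.diagnostics["costate_error"] = repr(exc)
    return sol
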