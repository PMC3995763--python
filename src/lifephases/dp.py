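"""Brute-force dynamic-programming oracle for the control problem.

Backward value iteration on a discretised (time, energy, knowledge) grid
with a finite control menu: one explicit-Euler step per stage per control,
bilinear interpolation of the next-stage value between grid nodes, and a
"death" value for any step that lands below the survival floor.  Death is
encoded as E_min - 1, strictly below every attainable terminal energy (a
live trajectory ends with E >= E_min) yet finite and of moderate size:
with -inf or an astronomically negative sentinel, bilinear blending lets a
single dead neighbour node poison the value of every nearby live state.
The forward greedy rollout from the initial state gives an independent
lower-bound estimate of the optimum used to cross-validate the collocation
solver; it is deliberately coarse and never the headline answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import BoundaryConstraints, ModelParams

__all__ = ["GridSpec", "DPResult", "dp_solve", "compare_with_ocp", "default_grid"]

def death_value(bc: BoundaryConstraints) -> float:
    """Value of falling below the survival floor: below any live outcome."""
    return bc.E_min - 1.0


@dataclass
class GridSpec:
    """Discretisation of the DP problem."""

    n_t: int
    E_grid: np.ndarray
    L_grid: np.ndarray
    u_levels: np.ndarray

    def __post_init__(self) -> None:
        self.E_grid = np.asarray(self.E_grid, dtype=float)
        self.L_grid = np.asarray(self.L_grid, dtype=float)
        self.u_levels = np.asarray(self.u_levels, dtype=float)
        if self.n_t < 50:
            raise ValueError("n_t must be >= 50")
        for name, g in (("E_grid", self.E_grid), ("L_grid", self.L_grid)):
            if g.size < 2 or not np.all(np.diff(g) > 0):
                raise ValueError(f"{name} must be strictly increasing with >= 2 levels")

    def validate_for(self, p: ModelParams, bc: BoundaryConstraints) -> None:
        import warnings

        ceiling = bc.control_ceiling(p)
        if not np.isclose(self.u_levels.min(), 0.0, atol=1e-12) and bc.u_min == 0.0:
            raise ValueError("u_levels must include 0")
        if self.u_levels.max() < ceiling - 1e-9:
            # restricted menus (e.g. {0} for closed-form checks) are useful
            # but cannot represent the full problem
            warnings.warn(
                "u_levels do not reach the control ceiling; the DP value is a "
                "lower bound for the restricted menu only",
                UserWarning,
                stacklevel=2,
            )
        L_star = p.alpha * ceiling / p.m_L
        if self.L_grid[-1] < L_star - 1e-9:
            raise ValueError(
                f"L grid upper bound {self.L_grid[-1]:g} does not cover the "
                f"reachable fixed point {L_star:g}"
            )


def default_grid(p: ModelParams, bc: BoundaryConstraints) -> GridSpec:
    """Desk-scale default: 200 stages, 80x80 state grid, 11 control levels.

    The energy grid spans [E_min, E_min + 10] (ample for the baseline
    parameter set) and the knowledge grid spans 1.25x the reachable fixed
    point alpha*ceiling/m_L.
    """
    ceiling = bc.control_ceiling(p)
    return GridSpec(
        n_t=200,
        E_grid=np.linspace(bc.E_min, bc.E_min + 10.0, 80),
        L_grid=np.linspace(0.0, 1.25 * p.alpha * ceiling / p.m_L, 80),
        u_levels=np.linspace(0.0, ceiling, 11),
    )


@dataclass
class DPResult:
    params: ModelParams
    constraints: BoundaryConstraints
    grid: GridSpec
    values: np.ndarray        # (n_t+1, nE, nL) value function, death = E_min - 1
    rollout_times: np.ndarray
    rollout_E: np.ndarray
    rollout_L: np.ndarray
    rollout_u: np.ndarray
    terminal_energy: float
    diagnostics: dict = field(default_factory=dict)


def _interp2(V, E_grid, L_grid, Eq, Lq, death):
    """Bilinear interpolation of V on the rectangle grid; death below the E floor.

    Queries above the grid are clamped (the value function is monotone in
    both states, so clamping can only understate the value slightly).
    """
    below = Eq < E_grid[0] - 1e-12
    Ec = np.clip(Eq, E_grid[0], E_grid[-1])
    Lc = np.clip(Lq, L_grid[0], L_grid[-1])
    iE = np.clip(np.searchsorted(E_grid, Ec) - 1, 0, E_grid.size - 2)
    iL = np.clip(np.searchsorted(L_grid, Lc) - 1, 0, L_grid.size - 2)
    wE = (Ec - E_grid[iE]) / (E_grid[iE + 1] - E_grid[iE])
    wL = (Lc - L_grid[iL]) / (L_grid[iL + 1] - L_grid[iL])
    out = (
        V[iE, iL] * (1 - wE) * (1 - wL)
        + V[iE + 1, iL] * wE * (1 - wL)
        + V[iE, iL + 1] * (1 - wE) * wL
        + V[iE + 1, iL + 1] * wE * wL
    )
    return np.where(below, death, out)


def dp_solve(
    p: ModelParams,
    bc: BoundaryConstraints,
    g: GridSpec | None = None,
    keep_values: bool = True,
) -> DPResult:
    """Backward value iteration plus forward greedy rollout.

    Terminal value V(T, E, L) = E.  Raises ``ValueError`` when the initial
    state lies outside the grid.
    """
    if g is None:
        g = default_grid(p, bc)
    g.validate_for(p, bc)
    Eg, Lg, ug = g.E_grid, g.L_grid, g.u_levels
    if not (Eg[0] - 1e-9 <= bc.E0 <= Eg[-1] + 1e-9) or not (
        Lg[0] - 1e-9 <= bc.L0 <= Lg[-1] + 1e-9
    ):
        raise ValueError("initial state (E0, L0) outside the DP grid")
    dt = p.T_max / g.n_t
    nE, nL = Eg.size, Lg.size
    death = death_value(bc)

    # per-control one-step Euler images of the whole grid; fE and fL do not
    # depend on E, so next-L is a vector over L and next-E is E plus an
    # L-dependent shift
    intake = p.f_max * Lg / (Lg + p.k_L)            # (nL,)
    V = np.broadcast_to(Eg[:, None], (nE, nL)).copy()
    values = np.empty((g.n_t + 1, nE, nL)) if keep_values else None
    if keep_values:
        values[g.n_t] = V

    EE = Eg[:, None]
    for it in range(g.n_t - 1, -1, -1):
        best = np.full((nE, nL), death)
        for u in ug:
            dE = dt * (intake - p.m - u)            # (nL,)
            Lnext = Lg + dt * (p.alpha * u - p.m_L * Lg)
            Enext = EE + dE[None, :]                # (nE, nL)
            cand = _interp2(V, Eg, Lg, Enext, np.broadcast_to(Lnext, (nE, nL)), death)
            np.maximum(best, cand, out=best)
        V = best
        if keep_values:
            values[it] = V

    # forward greedy rollout
    tgrid = np.linspace(0.0, p.T_max, g.n_t + 1)
    E_r = np.empty(g.n_t + 1)
    L_r = np.empty(g.n_t + 1)
    u_r = np.empty(g.n_t)
    E_r[0], L_r[0] = bc.E0, bc.L0
    Vs = values if keep_values else None
    for it in range(g.n_t):
        if keep_values:
            Vnext = values[it + 1]
        else:  # pragma: no cover - keep_values=False replays the recursion
            raise NotImplementedError("rollout requires keep_values=True")
        best_v, best_u = -np.inf, 0.0
        for u in ug:
            En = E_r[it] + dt * (
                p.f_max * L_r[it] / (L_r[it] + p.k_L) - p.m - u
            )
            Ln = L_r[it] + dt * (p.alpha * u - p.m_L * L_r[it])
            v = float(_interp2(Vnext, Eg, Lg, np.array([En]), np.array([Ln]), death)[0])
            if v > best_v + 1e-12:
                best_v, best_u = v, u
        u_r[it] = best_u
        E_r[it + 1] = E_r[it] + dt * (
            p.f_max * L_r[it] / (L_r[it] + p.k_L) - p.m - best_u
        )
        L_r[it + 1] = L_r[it] + dt * (p.alpha * best_u - p.m_L * L_r[it])

    return DPResult(
        params=p,
        constraints=bc,
        grid=g,
        values=values,
        rollout_times=tgrid,
        rollout_E=E_r,
        rollout_L=L_r,
        rollout_u=np.append(u_r, u_r[-1]),
        terminal_energy=float(E_r[-1]),
        diagnostics={
            "value_at_start": float(
                _interp2(values[0], Eg, Lg, np.array([bc.E0]), np.array([bc.L0]), death)[0]
            )
            if keep_values
            else None,
            "dt": dt,
        },
    )


def compare_with_ocp(sol, dp: DPResult, gap_tol: float = 0.05) -> dict:
    """Agreement report between a collocation Solution and the DP oracle.

    Raises ``ValueError`` when the two were computed for different
    parameters or boundary values.
    """
    if sol.params != dp.params or sol.constraints != dp.constraints:
        raise ValueError("solution and DP result were computed for different inputs")
    obj = sol.objective
    gap = abs(obj - dp.terminal_energy) / abs(obj)
    u_ocp = np.asarray(sol.control(dp.rollout_times), dtype=float)
    sup_dist = float(np.max(np.abs(u_ocp - dp.rollout_u)))
    return {
        "ocp_objective": obj,
        "dp_rollout_terminal_energy": dp.terminal_energy,
        "relative_gap": float(gap),
        "policy_sup_distance": sup_dist,
        "gap_tol": gap_tol,
        "pass": bool(gap <= gap_tol),
    }
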