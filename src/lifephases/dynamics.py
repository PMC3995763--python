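"""Rate laws, forward simulation and feasibility diagnostics.

The state equations are

    dE/dt = f_max * L / (L + k_L) - m - u(t)
    dL/dt = alpha * u(t) - m_L * L

with energy intake saturating in knowledge and the learning investment
``u`` entering linearly in both equations.  Forward simulation uses a
fixed-step classical Runge-Kutta (RK4) integrator: the right-hand sides are
smooth within control arcs, and a fixed step makes runs bit-reproducible.

Feasibility (survival floor, knowledge floor, control bounds) is *diagnosed*
here, never enforced: the integrator reports what the dynamics do under the
given strategy, and the optimiser owns constraint enforcement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import BoundaryConstraints, ModelParams

__all__ = [
    "ControlSchedule",
    "StateTrajectory",
    "FeasibilityReport",
    "energy_rate",
    "knowledge_rate",
    "simulate",
    "terminal_energy",
    "check_feasibility",
    "singular_knowledge_level",
    "sustainable_net_rate",
]


def singular_knowledge_level(p: ModelParams) -> float:
    """Knowledge level maximising the sustainable net energy rate.

    Maximises f_max*L/(L+k_L) - m - m_L*L/alpha over L >= 0 (intake minus
    living cost minus the investment that exactly offsets knowledge decay);
    the maximiser sqrt(alpha*f_max*k_L/m_L) - k_L, clipped at 0, is also the
    level the optimal strategy holds on its singular (maintenance) arc.
    """
    return max(0.0, math.sqrt(p.alpha * p.f_max * p.k_L / p.m_L) - p.k_L)


def sustainable_net_rate(p: ModelParams) -> float:
    """Best steady-state net energy gain rate (may be negative).

    Negative values mean no knowledge level pays for its own upkeep plus
    living costs: the subject can only survive on initial reserves, and for
    long enough lifetimes no feasible strategy exists at all.
    """
    L = singular_knowledge_level(p)
    return p.f_max * L / (L + p.k_L) - p.m - p.m_L * L / p.alpha

#: Default number of RK4 steps per lifetime (step = T_max / this).
DEFAULT_STEPS_PER_LIFE = 2000


def energy_rate(E: float, L, u, p: ModelParams):
    """Instantaneous energy change rate dE/dt.

    ``E`` itself does not enter the rate law (intake depends on knowledge
    only) but is accepted for signature symmetry.  Raises ``ValueError``
    on negative knowledge or learning investment.
    """
    L = np.asarray(L, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(L < 0):
        raise ValueError("knowledge L must be non-negative")
    if np.any(u < 0):
        raise ValueError("learning investment u must be non-negative")
    out = p.f_max * L / (L + p.k_L) - p.m - u
    return float(out) if out.ndim == 0 else out


def knowledge_rate(L, u, p: ModelParams):
    """Instantaneous knowledge change rate dL/dt = alpha*u - m_L*L."""
    L = np.asarray(L, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(L < 0):
        raise ValueError("knowledge L must be non-negative")
    if np.any(u < 0):
        raise ValueError("learning investment u must be non-negative")
    out = p.alpha * u - p.m_L * L
    return float(out) if out.ndim == 0 else out


@dataclass
class ControlSchedule:
    """A time-gridded learning-investment strategy u(t) on [0, T_max].

    ``interpolation`` declares how u is evaluated between grid points:
    ``"linear"`` (piecewise-linear, the default) or ``"previous"``
    (piecewise-constant, left-continuous zero-order hold -- natural for
    bang-bang strategies).
    """

    times: np.ndarray
    values: np.ndarray
    interpolation: str = "linear"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size < 1:
            raise ValueError("empty control schedule")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.interpolation not in ("linear", "previous"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")

    @property
    def t_final(self) -> float:
        return float(self.times[-1])

    def __call__(self, t):
        """Evaluate u(t); clamps t to [times[0], times[-1]]."""
        t = np.asarray(t, dtype=float)
        if self.interpolation == "linear":
            out = np.interp(t, self.times, self.values)
        else:
            idx = np.searchsorted(self.times, t, side="right") - 1
            idx = np.clip(idx, 0, self.values.size - 1)
            out = self.values[idx]
        return float(out) if out.ndim == 0 else out

    @classmethod
    def constant(cls, value: float, T_max: float) -> "ControlSchedule":
        return cls(np.array([0.0, T_max]), np.array([value, value]), "previous")

    @classmethod
    def bang(cls, t_switch: float, T_max: float, high: float, low: float = 0.0) -> "ControlSchedule":
        """Single-switch strategy: ``high`` on [0, t_switch), ``low`` after."""
        if not 0.0 <= t_switch <= T_max:
            raise ValueError(f"switch time {t_switch:g} outside [0, {T_max:g}]")
        return cls(
            np.array([0.0, t_switch, T_max]),
            np.array([high, low, low]),
            "previous",
        )


@dataclass
class StateTrajectory:
    """Time-gridded states (E(t), L(t))."""

    times: np.ndarray
    E_values: np.ndarray
    L_values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.E_values = np.asarray(self.E_values, dtype=float)
        self.L_values = np.asarray(self.L_values, dtype=float)
        if not (self.times.shape == self.E_values.shape == self.L_values.shape):
            raise ValueError("times, E_values, L_values must share a shape")

    def __len__(self) -> int:
        return self.times.size

    def E(self, t):
        return np.interp(t, self.times, self.E_values)

    def L(self, t):
        return np.interp(t, self.times, self.L_values)


def _rates(E, L, u, p: ModelParams):
    # unchecked fast path used inside the integrator
    return (p.f_max * L / (L + p.k_L) - p.m - u, p.alpha * u - p.m_L * L)


def simulate(
    p: ModelParams,
    bc: BoundaryConstraints,
    control: ControlSchedule,
    step: float | None = None,
) -> StateTrajectory:
    """Integrate the state equations under ``control`` from (E0, L0).

    Fixed-step RK4 on a uniform grid with step ``<= step`` (default
    ``T_max / 2000``).  Infeasible trajectories (energy under the survival
    floor, control out of bounds) are returned as-is; use
    :func:`check_feasibility` to diagnose them.
    """
    T = p.T_max
    if control.t_final < T - 1e-12:
        raise ValueError(
            f"control schedule ends at {control.t_final:g} < T_max={T:g}"
        )
    if step is None:
        step = T / DEFAULT_STEPS_PER_LIFE
    if step <= 0:
        raise ValueError("step must be positive")
    n = max(1, int(math.ceil(T / step - 1e-9)))
    times = np.linspace(0.0, T, n + 1)
    h = T / n
    E = np.empty(n + 1)
    L = np.empty(n + 1)
    E[0], L[0] = bc.E0, bc.L0
    for i in range(n):
        t = times[i]
        u0 = control(t)
        um = control(t + 0.5 * h)
        u1 = control(t + h)
        k1E, k1L = _rates(E[i], L[i], u0, p)
        k2E, k2L = _rates(E[i] + 0.5 * h * k1E, L[i] + 0.5 * h * k1L, um, p)
        k3E, k3L = _rates(E[i] + 0.5 * h * k2E, L[i] + 0.5 * h * k2L, um, p)
        k4E, k4L = _rates(E[i] + h * k3E, L[i] + h * k3L, u1, p)
        E[i + 1] = E[i] + (h / 6.0) * (k1E + 2 * k2E + 2 * k3E + k4E)
        L[i + 1] = L[i] + (h / 6.0) * (k1L + 2 * k2L + 2 * k3L + k4L)
    return StateTrajectory(times, E, L)


def terminal_energy(traj: StateTrajectory) -> float:
    """Energy at the final time point (the objective of the control problem)."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    return float(traj.E_values[-1])


@dataclass
class FeasibilityReport:
    """Grid-point constraint violations; empty ``violations`` means feasible."""

    violations: list[dict] = field(default_factory=list)
    tol: float = 1e-6

    @property
    def ok(self) -> bool:
        return not self.violations

    @property
    def worst(self) -> float:
        """Largest violation magnitude (0 when feasible)."""
        if not self.violations:
            return 0.0
        return max(v["excess"] for v in self.violations)

    def by_kind(self, kind: str) -> list[dict]:
        return [v for v in self.violations if v["kind"] == kind]

    def summary(self) -> str:
        if self.ok:
            return f"feasible (tol={self.tol:g})"
        kinds = sorted({v["kind"] for v in self.violations})
        parts = [f"{len(self.by_kind(k))} x {k}" for k in kinds]
        return (
            f"infeasible: {', '.join(parts)}; worst excess {self.worst:.3g} "
            f"(tol={self.tol:g})"
        )


def check_feasibility(
    traj: StateTrajectory,
    control: ControlSchedule,
    bc: BoundaryConstraints,
    p: ModelParams,
    tol: float = 1e-6,
) -> FeasibilityReport:
    """List every grid point violating a state or control constraint.

    Checks, at the trajectory grid points: E >= E_min - tol,
    L >= L_min - tol; and at the control grid points:
    u_min - tol <= u <= min(u_max, f_max) + tol.
    """
    rep = FeasibilityReport(tol=tol)
    ceiling = bc.control_ceiling(p)

    def _add(kind, idx, t, value, bound):
        rep.violations.append(
            {
                "kind": kind,
                "index": int(idx),
                "time": float(t),
                "value": float(value),
                "bound": float(bound),
                "excess": float(abs(value - bound)),
            }
        )

    for i in np.flatnonzero(traj.E_values < bc.E_min - tol):
        _add("E_floor", i, traj.times[i], traj.E_values[i], bc.E_min)
    for i in np.flatnonzero(traj.L_values < bc.L_min - tol):
        _add("L_floor", i, traj.times[i], traj.L_values[i], bc.L_min)
    for i in np.flatnonzero(control.values < bc.u_min - tol):
        _add("u_lower", i, control.times[i], control.values[i], bc.u_min)
    for i in np.flatnonzero(control.values > ceiling + tol):
        _add("u_upper", i, control.times[i], control.values[i], ceiling)
    return rep
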