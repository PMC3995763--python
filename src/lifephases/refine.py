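"""Arc-structure polish (switching-time optimization).

A uniform collocation mesh quantises the bang-bang switch times to mesh
nodes, which leaves an O(mesh)-scale wobble on the objective.  The polish
stage removes it: the arc sequence (ceiling / survival-floor / singular /
zero) is read off the converged collocation solution, each arc is replaced
by its exact feedback law,

* ceiling arc:  u = ceiling, rolled off smoothly onto the floor law as the
  survival floor approaches (so energy never undershoots the floor);
* floor arc:    u = intake - m + K*(E - E_min), the proportional law that
  pins energy to the survival floor;
* singular arc: u = m_L*L/alpha, the law that freezes knowledge at the
  level it enters the arc with;
* zero arc:     u = 0;

and the junction times become the only free variables, optimised by
Nelder-Mead on the finely integrated terminal energy.  The polished answer
is accepted only when it re-simulates at least as well as the collocation
control itself; otherwise the raw collocation solution stands.

The closed-loop integrator is a fixed-step RK4 kernel, JIT-compiled with
numba when available (pure-numpy fallback otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .params import BoundaryConstraints, ModelParams

__all__ = ["extract_arcs", "polish_arcs", "ArcSolution"]

ARC_CEILING, ARC_FLOOR, ARC_SINGULAR, ARC_ZERO = 0, 1, 2, 3


def _arc_kernel(
    n_steps, T, E0, L0, E_min, u_min, ceiling,
    f_max, k_L, m, alpha, m_L, bounds, arcs,
):
    h = T / n_steps
    K = 0.5 / h
    E = np.empty(n_steps + 1)
    L = np.empty(n_steps + 1)
    u_out = np.empty(n_steps + 1)
    E[0] = E0
    L[0] = L0
    n_arcs = arcs.shape[0]
    arc_idx = 0
    for i in range(n_steps):
        tm = (i + 0.5) * h
        while arc_idx < n_arcs - 1 and tm > bounds[arc_idx + 1]:
            arc_idx += 1
        arc = arcs[arc_idx]
        Ei = E[i]
        Li = L[i]
        # RK4 with the feedback law inlined at each stage
        k1E = 0.0; k1L = 0.0; k2E = 0.0; k2L = 0.0
        k3E = 0.0; k3L = 0.0; k4E = 0.0; k4L = 0.0
        for stage in range(4):
            if stage == 0:
                Es = Ei; Ls = Li
            elif stage == 1:
                Es = Ei + 0.5 * h * k1E; Ls = Li + 0.5 * h * k1L
            elif stage == 2:
                Es = Ei + 0.5 * h * k2E; Ls = Li + 0.5 * h * k2L
            else:
                Es = Ei + h * k3E; Ls = Li + h * k3L
            if Ls < 0.0:
                Ls = 0.0
            intake = f_max * Ls / (Ls + k_L)
            floor_u = intake - m + K * (Es - E_min)
            if arc == 0:        # ceiling
                u = ceiling if ceiling < floor_u else floor_u
            elif arc == 1:      # floor
                u = floor_u
            elif arc == 2:      # singular: hold knowledge
                us = m_L * Ls / alpha
                u = us if us < floor_u else floor_u
            else:               # zero
                u = 0.0
            if u < u_min:
                u = u_min
            if u > ceiling:
                u = ceiling
            dE = intake - m - u
            dL = alpha * u - m_L * Ls
            if stage == 0:
                k1E = dE; k1L = dL; u_out[i] = u
            elif stage == 1:
                k2E = dE; k2L = dL
            elif stage == 2:
                k3E = dE; k3L = dL
            else:
                k4E = dE; k4L = dL
        E[i + 1] = Ei + (h / 6.0) * (k1E + 2.0 * k2E + 2.0 * k3E + k4E)
        Lnew = Li + (h / 6.0) * (k1L + 2.0 * k2L + 2.0 * k3L + k4L)
        L[i + 1] = Lnew if Lnew > 0.0 else 0.0
    u_out[n_steps] = u_out[n_steps - 1]
    return E, L, u_out


try:  # JIT when numba is present; the kernel is pure scalar numerics
    from numba import njit as _njit

    _arc_kernel = _njit(cache=False)(_arc_kernel)
except ImportError:  # pragma: no cover - numba is an optional accelerator
    pass


@dataclass
class ArcSolution:
    """Polished trajectory on a fine uniform grid."""

    arcs: list[int]
    junctions: np.ndarray         # len(arcs)-1 interior junction times
    times: np.ndarray
    E: np.ndarray
    L: np.ndarray
    u: np.ndarray
    objective: float
    min_E: float
    nm_evals: int


def extract_arcs(times, E, u, p: ModelParams, bc: BoundaryConstraints):
    """Arc sequence and junction times from a mesh solution.

    Point rules (priority order): floor when E is pinned near E_min;
    ceiling when u is at the upper bound; zero when u vanishes; singular
    otherwise.  Single-node blips (and runs shorter than 0.2% of the
    lifetime) are merged forward; real arcs as short as two nodes survive,
    which matters for the brief all-in establishment burst on coarse or
    strongly graded meshes.
    """
    ceiling = bc.control_ceiling(p)
    tol_E = 0.02 * (bc.E0 - bc.E_min)
    tol_u = 0.02 * ceiling
    lab = np.full(times.size, ARC_SINGULAR)
    lab[u <= tol_u] = ARC_ZERO
    lab[u >= ceiling - tol_u] = ARC_CEILING
    lab[E <= bc.E_min + tol_E] = ARC_FLOOR

    runs = []
    for i, l in enumerate(lab):
        if runs and runs[-1][0] == l:
            runs[-1][2] = i
        else:
            runs.append([int(l), i, i])
    min_dur = 0.002 * p.T_max
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for k, r in enumerate(runs):
            if r[2] == r[1] or times[r[2]] - times[r[1]] < min_dur:
                if k + 1 < len(runs):
                    runs[k + 1][1] = r[1]
                else:
                    runs[k - 1][2] = r[2]
                del runs[k]
                changed = True
                break
        k = 0
        while k + 1 < len(runs):
            if runs[k][0] == runs[k + 1][0]:
                runs[k][2] = runs[k + 1][2]
                del runs[k + 1]
            else:
                k += 1
    arcs = [r[0] for r in runs]
    junctions = np.array(
        [0.5 * (times[runs[k][2]] + times[runs[k + 1][1]]) for k in range(len(runs) - 1)]
    )
    return arcs, junctions


def _simulate_arcs(p, bc, arcs, junctions, n_steps):
    """Closed-loop RK4 through the arc sequence."""
    bounds = np.concatenate([[0.0], np.asarray(junctions, dtype=float), [p.T_max]])
    E, L, u = _arc_kernel(
        int(n_steps), p.T_max, bc.E0, bc.L0, bc.E_min, bc.u_min,
        bc.control_ceiling(p), p.f_max, p.k_L, p.m, p.alpha, p.m_L,
        bounds, np.asarray(arcs, dtype=np.int64),
    )
    t = np.linspace(0.0, p.T_max, n_steps + 1)
    return t, E, L, u, float(np.min(E))


def polish_arcs(
    p: ModelParams,
    bc: BoundaryConstraints,
    arcs: list[int],
    junctions: np.ndarray,
    n_steps_opt: int = 1500,
    n_steps_final: int = 4000,
    max_arcs: int = 6,
) -> ArcSolution | None:
    """Optimise the junction times of a fixed arc sequence.

    Returns ``None`` when the sequence is implausibly long (collocation
    likely unconverged) -- callers then keep the raw mesh solution.
    """
    if not arcs or len(arcs) > max_arcs:
        return None
    T = p.T_max
    n_free = len(junctions)
    evals = 0

    def objective(theta):
        nonlocal evals
        evals += 1
        th = np.asarray(theta, dtype=float)
        if np.any(th < 0.0) or np.any(th > T) or np.any(np.diff(th) < 0.0):
            return 1e6
        _, E, _, _, minE = _simulate_arcs(p, bc, arcs, th, n_steps_opt)
        pen = 1e3 * max(0.0, bc.E_min - minE)
        return -E[-1] + pen

    if n_free:
        theta = np.asarray(junctions, dtype=float)
        f_prev = np.inf
        for _ in range(2):  # one restart guards against simplex collapse
            res = minimize(
                objective,
                theta,
                method="Nelder-Mead",
                options={
                    "xatol": 1e-6 * T,
                    "fatol": 1e-10,
                    "maxfev": 200 * max(1, n_free),
                    "initial_simplex": _simplex(theta, T),
                },
            )
            theta = np.sort(np.clip(res.x, 0.0, T))
            if f_prev - res.fun < 1e-9:
                break
            f_prev = res.fun
    else:
        theta = np.asarray(junctions, dtype=float)
    t, E, L, u, minE = _simulate_arcs(p, bc, arcs, theta, n_steps_final)
    return ArcSolution(
        arcs=list(arcs),
        junctions=theta,
        times=t,
        E=E,
        L=L,
        u=u,
        objective=float(E[-1]),
        min_E=minE,
        nm_evals=evals,
    )


def _simplex(theta0, T):
    n = theta0.size
    simplex = np.tile(theta0, (n + 1, 1))
    step = 0.02 * T
    for k in range(n):
        simplex[k + 1, k] = np.clip(simplex[k + 1, k] + step, 0.0, T)
    return simplex
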