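"""First-order optimality diagnostics (Pontryagin conditions).

The Hamiltonian of the terminal-energy problem is

    H = lambda_E * (f_max*L/(L+k_L) - m - u) + lambda_L * (alpha*u - m_L*L)

with terminal costates lambda_E(T) = 1 (the objective is terminal energy)
and lambda_L(T) = 0 (leftover knowledge is worthless at death).  Since H
has no explicit E-dependence, lambda_E is constant wherever the survival
floor E >= E_min is inactive.  On an active floor arc the control is
interior, which pins the switching function

    sigma(t) = dH/du = alpha*lambda_L(t) - lambda_E(t)

to zero there (lambda_L = lambda_E/alpha), and consistency of the two
adjoint equations yields a floor multiplier

    eta(t) = lambda_E * (alpha * f_max*k_L/(L+k_L)^2 - m_L) >= 0,
    dlambda_E/dt = -eta

so the shadow price of energy falls while learning is rationed by survival.
Off the floor, lambda_L obeys

    dlambda_L/dt = -lambda_E * f_max*k_L/(L+k_L)^2 + m_L*lambda_L.

Because u enters H linearly, the maximum principle dictates bang-bang
control off singular/constrained arcs: u at the ceiling where sigma > 0,
u = 0 where sigma < 0.  ``check_pmp`` scores a solved trajectory against
that rule on its bang arcs.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams

__all__ = ["estimate_costates", "switching_function", "check_pmp"]


def _dfE_dL(L, p: ModelParams):
    return p.f_max * p.k_L / (L + p.k_L) ** 2


def estimate_costates(sol, p: ModelParams, active_tol: float | None = None):
    """Backward-integrate the adjoint equations along a solved trajectory.

    Attaches ``lambda_E``, ``lambda_L``, ``sigma`` and the floor multiplier
    ``eta`` (nonzero only on the active survival-floor arc) to
    ``sol.costates`` and returns that dict.  Raises ``ValueError`` when the
    solution is infeasible at tolerance 1e-4.
    """
    rep = sol.feasibility(tol=1e-4)
    if not rep.ok:
        raise ValueError(f"cannot estimate costates: {rep.summary()}")
    bc = sol.constraints
    t = sol.states.times
    L_nodes = sol.states.L_values
    E_nodes = sol.states.E_values
    n = t.size
    if active_tol is None:
        active_tol = 1e-4 * (bc.E0 - bc.E_min)
    active = E_nodes <= bc.E_min + active_tol

    lam_E = np.empty(n)
    lam_L = np.empty(n)
    eta = np.zeros(n)
    lam_E[-1], lam_L[-1] = 1.0, 0.0

    def dlamL(lE, lL, L):
        return -lE * _dfE_dL(L, p) + p.m_L * lL

    nsub = 4 if n < 1000 else 1  # RK4 substeps per mesh interval
    for i in range(n - 1, 0, -1):
        h = (t[i] - t[i - 1]) / nsub
        lE, lL = lam_E[i], lam_L[i]
        on_floor = active[i] and active[i - 1]
        if on_floor:
            # sigma == 0 arc: lambda_L tracks lambda_E/alpha, lambda_E obeys
            # dlambda_E/dt = -eta backward
            lL = lE / p.alpha
            for k in range(nsub):
                # backward step of dlE/dt = -lE*(alpha*fE' - mL)
                tt = t[i] - k * h
                def g(lEv, tau):
                    Lv = np.interp(tau, t, L_nodes)
                    return -lEv * (p.alpha * _dfE_dL(Lv, p) - p.m_L)
                k1 = g(lE, tt)
                k2 = g(lE - 0.5 * h * k1, tt - 0.5 * h)
                k3 = g(lE - 0.5 * h * k2, tt - 0.5 * h)
                k4 = g(lE - h * k3, tt - h)
                lE = lE - (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            lL = lE / p.alpha
            Lhere = L_nodes[i - 1]
            eta[i - 1] = lE * (p.alpha * _dfE_dL(Lhere, p) - p.m_L)
        else:
            for k in range(nsub):
                tt = t[i] - k * h
                def gL(lLv, tau):
                    Lv = np.interp(tau, t, L_nodes)
                    return dlamL(lE, lLv, Lv)
                k1 = gL(lL, tt)
                k2 = gL(lL - 0.5 * h * k1, tt - 0.5 * h)
                k3 = gL(lL - 0.5 * h * k2, tt - 0.5 * h)
                k4 = gL(lL - h * k3, tt - h)
                lL = lL - (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        lam_E[i - 1], lam_L[i - 1] = lE, lL

    sigma = p.alpha * lam_L - lam_E
    sol.costates = {
        "lambda_E": lam_E,
        "lambda_L": lam_L,
        "sigma": sigma,
        "eta": eta,
        "active_floor": active,
    }
    return sol.costates


def switching_function(sol, t):
    """sigma(t) = alpha*lambda_L(t) - lambda_E(t), interpolated on the mesh."""
    if not sol.costates:
        raise ValueError("costates not available; run estimate_costates first")
    t = np.asarray(t, dtype=float)
    T = sol.states.times[-1]
    if np.any(t < -1e-12) or np.any(t > T + 1e-12):
        raise ValueError(f"time outside [0, {T:g}]")
    out = np.interp(t, sol.states.times, sol.costates["sigma"])
    return float(out) if out.ndim == 0 else out


def check_pmp(
    sol,
    tol: float = 1e-2,
    u_tol: float | None = None,
    boundary_layer: int = 2,
) -> dict:
    """Score the bang-bang rule sigma > tol => u at ceiling, sigma < -tol =>
    u = 0 over the solution's bang arcs.

    Points where the rule does not constrain the control are excluded on
    the costates' own evidence: |sigma| <= tol (singular arcs, where any
    interior control is first-order consistent) and active survival-floor
    points (where the control is dictated by the state constraint, and
    sigma is pinned to zero anyway).  A ``boundary_layer``-point window
    around every arc junction is also excluded, since a switch smeared
    over one mesh interval is a discretisation artefact, not a first-order
    violation.  Passes when at least 95% of the remaining points obey the
    rule.
    """
    if not sol.costates:
        raise ValueError("costates not available; run estimate_costates first")
    p, bc = sol.params, sol.constraints
    ceiling = bc.control_ceiling(p)
    if u_tol is None:
        u_tol = 0.01 * ceiling
    t = sol.states.times
    u = np.asarray(sol.control(t), dtype=float)
    sigma = sol.costates["sigma"]
    E = sol.states.E_values

    active = E <= bc.E_min + 1e-4 * (bc.E0 - bc.E_min)
    singular = np.abs(sigma) <= tol
    excluded = active | singular
    # exclude a small window wherever the arc regime changes
    regime = np.where(excluded, 0, np.where(sigma > 0, 1, -1))
    change = np.flatnonzero(np.diff(regime) != 0)
    for j in change:
        lo = max(0, j - boundary_layer + 1)
        hi = min(t.size, j + boundary_layer + 1)
        excluded[lo:hi] = True

    checked = ~excluded
    n_checked = int(np.count_nonzero(checked))
    ok = np.ones(t.size, dtype=bool)
    hi_mask = sigma > tol
    lo_mask = sigma < -tol
    ok[hi_mask] = u[hi_mask] >= ceiling - u_tol
    ok[lo_mask] = u[lo_mask] <= bc.u_min + u_tol
    n_viol = int(np.count_nonzero(checked & ~ok))
    frac = 1.0 if n_checked == 0 else 1.0 - n_viol / n_checked
    return {
        "fraction_consistent": frac,
        "n_checked": n_checked,
        "n_violations": n_viol,
        "pass": bool(frac >= 0.95),
        "sigma_tol": tol,
        "u_tol": u_tol,
    }
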