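"""Segmentation of a solved lifetime into the four knowledge phases.

A solved strategy partitions the lifetime into up to four phases, always in
the same order when present:

* **establishment** -- all-in exploration: u at the ceiling while energy
  reserves are still above the survival floor;
* **accumulation** -- learning rationed by survival: energy pinned at the
  floor, intake just covering maintenance plus the learning spend;
* **maintenance** -- knowledge held at its optimal level: interior u
  balancing decay (dL/dt ~ 0);
* **exploitation** -- zero learning investment, harvesting only.

Each mesh point is labelled by the first matching rule (establishment,
then accumulation, then exploitation, then maintenance); unmatched points
-- transition layers, mostly -- are absorbed into the adjacent segment with
the nearer boundary, and runs shorter than a minimum duration are merged
forward.  Tolerances are scale-free by default (fractions of the control
ceiling, the initial reserve and the knowledge range).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import StateTrajectory, ControlSchedule
from .params import BoundaryConstraints, ModelParams

__all__ = [
    "PHASE_ORDER",
    "PhaseTolerances",
    "PhaseSegmentation",
    "classify_phases",
    "phase_fractions",
]

PHASE_ORDER = ("establishment", "accumulation", "maintenance", "exploitation")


@dataclass(frozen=True)
class PhaseTolerances:
    """Classification tolerances; ``None`` fields get scale-free defaults.

    eps_u : control tolerance (defaults to 1% of the ceiling)
    eps_E : energy-floor tolerance (defaults to 2% of E0 - E_min)
    eps_L : |dL/dt| tolerance (defaults to 1% of max L over the trajectory
            per unit lifetime)
    min_duration : minimum segment length (defaults to T_max/100)
    """

    eps_u: float | None = None
    eps_E: float | None = None
    eps_L: float | None = None
    min_duration: float | None = None

    def resolved(
        self, p: ModelParams, bc: BoundaryConstraints, L_max: float
    ) -> dict[str, float]:
        ceiling = bc.control_ceiling(p)
        return {
            "eps_u": self.eps_u if self.eps_u is not None else 0.01 * ceiling,
            "eps_E": self.eps_E if self.eps_E is not None else 0.02 * (bc.E0 - bc.E_min),
            "eps_L": self.eps_L
            if self.eps_L is not None
            else 0.01 * max(L_max, 1e-12) / p.T_max,
            "min_duration": self.min_duration
            if self.min_duration is not None
            else p.T_max / 100.0,
        }


@dataclass
class PhaseSegmentation:
    """Ordered, contiguous, non-overlapping segments covering [0, T_max]."""

    segments: list[tuple[str, float, float]]
    tolerances: dict[str, float] = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return [s[0] for s in self.segments]

    def duration(self, label: str) -> float:
        return sum(t1 - t0 for lbl, t0, t1 in self.segments if lbl == label)

    def segment_for(self, label: str) -> tuple[float, float] | None:
        for lbl, t0, t1 in self.segments:
            if lbl == label:
                return (t0, t1)
        return None

    def is_canonical(self) -> bool:
        """Labels form a subsequence of the canonical order, none repeated."""
        idx = [PHASE_ORDER.index(l) for l in self.labels if l in PHASE_ORDER]
        return (
            len(idx) == len(self.labels)
            and all(b > a for a, b in zip(idx, idx[1:]))
        )

    def to_records(self) -> list[dict]:
        return [
            {"label": lbl, "t_start": t0, "t_end": t1}
            for lbl, t0, t1 in self.segments
        ]


def _label_points(t, E, u, dLdt, bc, ceiling, tol):
    """Per-point rule labels; -1 marks unmatched points."""
    lab = np.full(t.size, -1, dtype=int)
    est = (u >= ceiling - tol["eps_u"]) & (E > bc.E_min + tol["eps_E"])
    acc = E <= bc.E_min + tol["eps_E"]
    expl = u <= bc.u_min + tol["eps_u"]
    maint = np.abs(dLdt) <= tol["eps_L"]
    lab[maint] = 2
    lab[expl] = 3
    lab[acc] = 1
    lab[est] = 0
    # precedence: establishment > accumulation > exploitation > maintenance,
    # applied by assigning in reverse priority above
    return lab


def classify_phases(
    sol,
    bc: BoundaryConstraints | None = None,
    tolerances: PhaseTolerances | None = None,
) -> PhaseSegmentation:
    """Segment a solved trajectory into knowledge phases.

    ``sol`` may be a :class:`~lifephases.collocation.Solution` or any object
    with ``params``, ``constraints``, ``states`` and ``control`` attributes.
    Raises ``ValueError`` for empty or infeasible (at 1e-4) solutions.
    """
    p: ModelParams = sol.params
    if bc is None:
        bc = sol.constraints
    states: StateTrajectory = sol.states
    control: ControlSchedule = sol.control
    if len(states) < 2:
        raise ValueError("cannot classify an empty or single-point solution")
    rep = sol.feasibility(tol=1e-4) if hasattr(sol, "feasibility") else None
    if rep is not None and not rep.ok:
        raise ValueError(f"cannot classify an infeasible solution: {rep.summary()}")

    t = states.times
    E = states.E_values
    L = states.L_values
    u = np.asarray(control(t), dtype=float)
    # rate-law derivative, not numerical differencing: immune to grid noise
    dLdt = p.alpha * u - p.m_L * L

    if tolerances is None:
        tolerances = PhaseTolerances()
    tol = tolerances.resolved(p, bc, float(np.max(L)))
    ceiling = bc.control_ceiling(p)

    lab = _label_points(t, E, u, dLdt, bc, ceiling, tol)

    # absorb unmatched points into the adjacent labelled segment with the
    # nearer boundary
    if np.all(lab == -1):
        raise ValueError("no phase rule matched any point")
    idx_lab = np.flatnonzero(lab >= 0)
    for i in np.flatnonzero(lab == -1):
        j = idx_lab[np.argmin(np.abs(idx_lab - i))]
        lab[i] = lab[j]

    # build runs
    runs: list[list] = []  # [label, i_start, i_end] inclusive indices
    for i, l in enumerate(lab):
        if runs and runs[-1][0] == l:
            runs[-1][2] = i
        else:
            runs.append([int(l), i, i])

    def run_dur(r):
        return t[r[2]] - t[r[1]]

    # merge runs shorter than the minimum duration forward (into the next
    # run when one exists, else backward), then coalesce equal neighbours
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for k, r in enumerate(runs):
            if run_dur(r) < tol["min_duration"]:
                if k + 1 < len(runs):
                    runs[k + 1][1] = r[1]
                else:
                    runs[k - 1][2] = r[2]
                del runs[k]
                changed = True
                break
        # coalesce
        k = 0
        while k + 1 < len(runs):
            if runs[k][0] == runs[k + 1][0]:
                runs[k][2] = runs[k + 1][2]
                del runs[k + 1]
            else:
                k += 1

    # enforce canonical subsequence order: while an out-of-order or repeated
    # label survives, merge the shortest offending run into its neighbour
    def order_ok(rs):
        idx = [r[0] for r in rs]
        return all(b > a for a, b in zip(idx, idx[1:]))

    while len(runs) > 1 and not order_ok(runs):
        offenders = [
            k
            for k in range(1, len(runs))
            if runs[k][0] <= runs[k - 1][0]
        ]
        k = min(offenders, key=lambda k: min(run_dur(runs[k]), run_dur(runs[k - 1])))
        a, b = runs[k - 1], runs[k]
        keep = a if run_dur(a) >= run_dur(b) else b
        a[0] = keep[0]
        a[2] = b[2]
        del runs[k]
        k = 0
        while k + 1 < len(runs):
            if runs[k][0] == runs[k + 1][0]:
                runs[k][2] = runs[k + 1][2]
                del runs[k + 1]
            else:
                k += 1

    # segment boundaries at midpoints between adjacent runs; cover [0, T]
    segments: list[tuple[str, float, float]] = []
    T = float(t[-1])
    for k, r in enumerate(runs):
        t0 = 0.0 if k == 0 else segments[-1][2]
        t1 = T if k == len(runs) - 1 else 0.5 * (t[r[2]] + t[runs[k + 1][1]])
        segments.append((PHASE_ORDER[r[0]], t0, t1))
    return PhaseSegmentation(segments, tolerances=tol)


def phase_fractions(seg: PhaseSegmentation, T_max: float) -> dict[str, float]:
    """Per-label durations divided by T_max; absent labels get 0."""
    fr = {lbl: seg.duration(lbl) / T_max for lbl in PHASE_ORDER}
    return fr
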