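"""Phase-structure parameter sweeps over normalized age.

For each value of one swept parameter (T_max, m_L, k_L or alpha, all other
constants at the baseline), the control problem is re-solved, the solution
is segmented into knowledge phases, and segment times are normalized by
that cell's lifetime, yielding the phase-diagram view: phase composition as
a function of age (0-1) against the environmental/life-history axis.

Cells are solved at a reduced mesh (half the configured baseline) with one
refinement round; any cell whose solution fails the first-order
(Pontryagin) consistency check is re-solved at the full mesh.  Per-cell
failures are recorded and the sweep continues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .collocation import SolverOptions, solve_ocp
from .params import BoundaryConstraints, ModelParams, PARAM_SWEEP_RANGES, SWEEPABLE_PARAMS
from .phases import PHASE_ORDER, PhaseSegmentation, PhaseTolerances, classify_phases, phase_fractions
from .pmp import check_pmp

__all__ = ["SweepResult", "sweep_parameter", "sweep_to_table", "default_sweep_values"]

#: Number of cells in a default sweep.
DEFAULT_SWEEP_CELLS = 16

#: Axes swept on a log scale (they span decades); the others are linear.
LOG_SCALE_PARAMS = ("k_L", "m_L")


def default_sweep_values(name: str, n: int = DEFAULT_SWEEP_CELLS) -> np.ndarray:
    """Default grid spanning the published range of one sweepable parameter."""
    if name not in SWEEPABLE_PARAMS:
        raise ValueError(
            f"parameter {name!r} is not sweepable (choose from {SWEEPABLE_PARAMS})"
        )
    lo, hi = PARAM_SWEEP_RANGES[name]
    if name in LOG_SCALE_PARAMS:
        return np.geomspace(lo, hi, n)
    return np.linspace(lo, hi, n)


@dataclass
class SweepCell:
    value: float
    status: str                       # "ok" or "failed:<reason>"
    segmentation: PhaseSegmentation | None
    fractions: dict[str, float]
    diagnostics: dict = field(default_factory=dict)


@dataclass
class SweepResult:
    name: str
    values: np.ndarray
    cells: list[SweepCell]
    base_params: ModelParams
    constraints: BoundaryConstraints
    options: SolverOptions

    @property
    def ok(self) -> bool:
        return all(c.status == "ok" for c in self.cells)

    def fractions_frame(self) -> pd.DataFrame:
        rows = {c.value: c.fractions for c in self.cells}
        return pd.DataFrame(rows).T.reindex(columns=list(PHASE_ORDER))


def sweep_parameter(
    name: str,
    values=None,
    base: ModelParams | None = None,
    bc: BoundaryConstraints | None = None,
    opts: SolverOptions | None = None,
    tolerances: PhaseTolerances | None = None,
) -> SweepResult:
    """Solve + classify across one parameter axis.

    ``values`` outside the published range are allowed (the parameter
    container warns).  Solver failures and infeasible/unclassifiable cells
    get ``status="failed:..."`` with empty fractions; the sweep continues.
    """
    if values is None:
        values = default_sweep_values(name)
    values = np.asarray(values, dtype=float)
    if name not in SWEEPABLE_PARAMS:
        raise ValueError(
            f"parameter {name!r} is not sweepable (choose from {SWEEPABLE_PARAMS})"
        )
    base = base if base is not None else ModelParams()
    bc = bc if bc is not None else BoundaryConstraints()
    opts = opts if opts is not None else SolverOptions()
    cell_opts = opts.replace(mesh=max(20, opts.mesh // 2), refinement_rounds=1)

    cells: list[SweepCell] = []
    for v in values:
        p = base.replace(**{name: float(v)})
        cell = _solve_cell(p, bc, cell_opts, opts, tolerances)
        cell.value = float(v)
        cells.append(cell)
    return SweepResult(name, values, cells, base, bc, opts)


def _solve_cell(p, bc, cell_opts, full_opts, tolerances) -> SweepCell:
    sol = solve_ocp(p, bc, cell_opts)
    needs_full = not sol.converged
    if sol.converged:
        try:
            pmp_ok = check_pmp(sol)["pass"]
        except Exception:
            pmp_ok = False
        needs_full = not pmp_ok
    if needs_full:
        sol = solve_ocp(p, bc, full_opts)
    if not sol.converged:
        return SweepCell(
            np.nan,
            f"failed:{sol.diagnostics.get('status', 'unknown')}",
            None,
            {lbl: np.nan for lbl in PHASE_ORDER},
            diagnostics=dict(sol.diagnostics),
        )
    try:
        seg = classify_phases(sol, bc, tolerances)
    except ValueError as exc:
        return SweepCell(
            np.nan,
            f"failed:classify:{exc}",
            None,
            {lbl: np.nan for lbl in PHASE_ORDER},
            diagnostics=dict(sol.diagnostics),
        )
    fr = phase_fractions(seg, p.T_max)
    # normalize segment times by this cell's lifetime
    norm = PhaseSegmentation(
        [(lbl, t0 / p.T_max, t1 / p.T_max) for lbl, t0, t1 in seg.segments],
        tolerances=seg.tolerances,
    )
    return SweepCell(
        np.nan,
        "ok",
        norm,
        fr,
        diagnostics={
            "objective": sol.objective,
            "mesh": sol.diagnostics.get("mesh"),
            "refined_full": needs_full,
        },
    )


def sweep_to_table(res: SweepResult) -> pd.DataFrame:
    """Long-format records: one row per (parameter value, phase label).

    Absent phases get fraction 0 with an empty (NaN) interval; failed cells
    get NaN fractions.  Ordering is bit-stable: ascending parameter value,
    then canonical phase order.
    """
    rows = []
    for cell in res.cells:
        for lbl in PHASE_ORDER:
            start = end = np.nan
            frac = cell.fractions.get(lbl, np.nan)
            if cell.segmentation is not None:
                span = cell.segmentation.segment_for(lbl)
                if span is not None:
                    start, end = span
                else:
                    frac = 0.0
            rows.append(
                {
                    "param_name": res.name,
                    "param_value": cell.value,
                    "phase": lbl,
                    "frac": frac,
                    "start_norm": start,
                    "end_norm": end,
                    "status": cell.status,
                }
            )
    return pd.DataFrame(rows)
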