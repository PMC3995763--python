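"""Shared fixtures: the baseline problem is solved once per session."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import lifephases as lp


@pytest.fixture(scope="session")
def baseline_model() -> lp.LifetimeExplorationModel:
    return lp.LifetimeExplorationModel()


@pytest.fixture(scope="session")
def baseline_results(baseline_model):
    """Full-accuracy solve of the baseline problem (default options)."""
    res = baseline_model.fit()
    assert res.converged, res.diagnostics
    return res


@pytest.fixture(scope="session")
def baseline_dp(baseline_model):
    """DP oracle on the default desk-scale grid."""
    return baseline_model.dp_solve()


@pytest.fixture(scope="session")
def fast_opts() -> lp.SolverOptions:
    """Reduced-accuracy options for solves where only structure matters."""
    return lp.SolverOptions(mesh=24, refinement_rounds=0, n_multistart=2)


@pytest.fixture(autouse=True)
def _silence_range_warnings():
    """Parameter values outside the published ranges warn by design; tests
    probe those edges deliberately."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


def make_solution(p, bc, times, E, L, u, interpolation="linear"):
    """Assemble a Solution object from raw arrays (for classifier/PMP tests)."""
    states = lp.StateTrajectory(np.asarray(times, float), np.asarray(E, float), np.asarray(L, float))
    control = lp.ControlSchedule(np.asarray(times, float), np.asarray(u, float), interpolation)
    return lp.Solution(
        params=p,
        constraints=bc,
        options=lp.SolverOptions(),
        control=control,
        states=states,
        objective=float(states.E_values[-1]),
    )
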