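"""Phase classification: constructed trajectories with known segmentations."""

import numpy as np
import pytest

import lifephases as lp
from lifephases.phases import PHASE_ORDER

from conftest import make_solution

P = lp.ModelParams()
BC = lp.BoundaryConstraints()


def four_phase_solution(n=2001):
    """Hand-built trajectory satisfying each labelling rule exactly:
    u=1 on [0,2); energy pinned at the floor with u = intake - m on [2,10);
    knowledge frozen (u = m_L*L/alpha) on [10,16); u=0 on [16,20]."""
    t = np.linspace(0.0, 20.0, n)
    E = np.empty(n)
    L = np.empty(n)
    u = np.empty(n)
    L_hold = 2.0
    for i, ti in enumerate(t):
        if ti < 2.0:
            E[i] = 5.5 - 0.3 * ti / 2.0     # stays clear of the floor band
            L[i] = 0.5 + 0.75 * ti          # rising under full investment
            u[i] = 1.0
        elif ti < 10.0:
            E[i] = 5.0
            L[i] = L_hold * (ti - 2.0) / 8.0 + 0.5 * (10.0 - ti) / 8.0
            u[i] = P.f_max * L[i] / (L[i] + P.k_L) - P.m
        elif ti < 16.0:
            E[i] = 5.0 + 3.0 * (ti - 10.0) / 6.0
            L[i] = L_hold
            u[i] = P.m_L * L_hold / P.alpha
        else:
            E[i] = 8.0
            L[i] = L_hold
            u[i] = 0.0
    return make_solution(P, BC, t, E, L, u)


class TestClassifier:
    def test_constructed_four_phase_trajectory(self):
        seg = lp.classify_phases(four_phase_solution())
        assert seg.labels == list(PHASE_ORDER)
        bounds = [s[1] for s in seg.segments] + [seg.segments[-1][2]]
        assert bounds == pytest.approx([0.0, 2.0, 10.0, 16.0, 20.0], abs=0.05)

    def test_fractions_of_constructed_trajectory(self):
        seg = lp.classify_phases(four_phase_solution())
        fr = lp.phase_fractions(seg, 20.0)
        assert [fr[l] for l in PHASE_ORDER] == pytest.approx(
            [0.1, 0.4, 0.3, 0.2], abs=3e-3
        )
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-12)

    def test_classification_is_idempotent(self):
        sol = four_phase_solution()
        seg1 = lp.classify_phases(sol)
        seg2 = lp.classify_phases(sol)
        assert seg1.segments == seg2.segments

    def test_zero_strategy_is_pure_exploitation(self):
        t = np.linspace(0.0, 20.0, 500)
        sol = make_solution(P, BC, t, 5.5 - 0.02 * t, np.zeros_like(t), np.zeros_like(t))
        seg = lp.classify_phases(sol)
        assert seg.labels == ["exploitation"]
        assert lp.phase_fractions(seg, 20.0)["exploitation"] == pytest.approx(1.0)

    def test_segments_are_contiguous_and_cover_lifetime(self):
        seg = lp.classify_phases(four_phase_solution())
        assert seg.segments[0][1] == 0.0
        assert seg.segments[-1][2] == 20.0
        for (_, _, t1), (_, t0, _) in zip(seg.segments, seg.segments[1:]):
            assert t0 == t1

    def test_infeasible_solution_rejected(self):
        t = np.linspace(0.0, 20.0, 100)
        sol = make_solution(P, BC, t, np.full_like(t, 4.0), np.zeros_like(t), np.zeros_like(t))
        with pytest.raises(ValueError, match="infeasible"):
            lp.classify_phases(sol)

    def test_single_point_solution_rejected(self):
        sol = make_solution(P, BC, [0.0], [5.5], [0.0], [0.0])
        with pytest.raises(ValueError):
            lp.classify_phases(sol)

    def test_short_transition_blips_are_merged(self):
        """A few unmatched transition points must not create segments."""
        sol = four_phase_solution()
        t = sol.states.times
        u = np.asarray(sol.control(t)).copy()
        # smear the final switch over ~0.1 time units
        j = np.searchsorted(t, 16.0)
        u[j : j + 10] = np.linspace(u[j], 0.0, 10)
        sol2 = make_solution(P, BC, t, sol.states.E_values, sol.states.L_values, u)
        seg = lp.classify_phases(sol2)
        assert seg.labels == list(PHASE_ORDER)

    def test_canonical_order_helper(self):
        good = lp.PhaseSegmentation([("establishment", 0, 1), ("exploitation", 1, 2)])
        bad = lp.PhaseSegmentation([("maintenance", 0, 1), ("accumulation", 1, 2)])
        rep = lp.PhaseSegmentation([("exploitation", 0, 1), ("exploitation", 1, 2)])
        assert good.is_canonical()
        assert not bad.is_canonical()
        assert not rep.is_canonical()


class TestFractions:
    def test_absent_labels_get_zero(self):
        seg = lp.PhaseSegmentation([("exploitation", 0.0, 20.0)])
        fr = lp.phase_fractions(seg, 20.0)
        assert fr["establishment"] == 0.0
        assert fr["exploitation"] == 1.0

    def test_fractions_sum_to_one(self):
        seg = lp.PhaseSegmentation(
            [("establishment", 0.0, 1.7), ("maintenance", 1.7, 12.3), ("exploitation", 12.3, 20.0)]
        )
        assert sum(lp.phase_fractions(seg, 20.0).values()) == pytest.approx(1.0, abs=1e-12)
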