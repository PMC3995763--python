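# Methods

## Model

States: energy `E(t)` and knowledge `L(t)` on a fixed lifetime `[0, T_max]`;
control: the learning-investment rate `u(t)`.

    dE/dt = f_max · L/(L + k_L) − m − u        E(0) = E0
    dL/dt = α·u − m_L·L                        L(0) = L0

subject to `E(t) ≥ E_min`, `L(t) ≥ L_min` and
`u_min ≤ u ≤ min(u_max, f_max)`; objective: maximise `E(T_max)`.

`u` is treated as an energy-expenditure rate (units E/t) rather than a
dimensionless time share: the published parameter table gives it E/t units
and bounds it by the maximal acquisition rate `f_max`, and the energy cost
of learning enters with coefficient one (any separate cost constant is
absorbed into the units of `α`).  The effective control ceiling is
`min(u_max, f_max)`, honouring both printed bounds at once.  `L ≥ 0` is
automatic for `L0 ≥ 0, u ≥ 0` since knowledge decay is proportional to `L`.

Parameters (defaults = the worked baseline; published sweep ranges in
brackets; out-of-range values warn, never error):

| name   | default | range        | units | meaning                          |
|--------|---------|--------------|-------|----------------------------------|
| f_max  | 1       | [0.5, 10]    | E/t   | maximal energy intake rate       |
| k_L    | 1       | [0.001, 10]  | L     | half-saturation knowledge        |
| m      | 0.02    | fixed        | E/t   | maintenance (living) cost        |
| α      | 1       | [0.5, 10]    | L/E   | learning efficiency              |
| m_L    | 0.08    | [0.01, 1]    | 1/t   | knowledge decay rate             |
| T_max  | 20      | [5, 100]     | t     | lifetime                         |

Boundary values: `E0 = 5.5`, `L0 = 0`, `E_min = 5`, `L_min = 0`,
`u ∈ [0, 1]`.

Two closed forms anchor everything else:

* singular knowledge level `L* = √(α·f_max·k_L/m_L) − k_L` (clipped at 0) —
  the unique maximiser of the sustainable net rate
  `r(L) = f_max·L/(L+k_L) − m − m_L·L/α`;
* viability: when `r(L*) ≤ 0` no knowledge level pays for itself, the
  subject lives off reserves, and lifetimes with `m·T_max > E0 − E_min`
  (roughly) admit **no** feasible strategy at all.  Such corners exist
  inside the published parameter box; the solver reports explicit failure
  there, and box-wide property tests sample conditioned on `r(L*) > 0`.

## First-order (Pontryagin) structure

Hamiltonian `H = λ_E·(f_max·L/(L+k_L) − m − u) + λ_L·(α·u − m_L·L)` with
terminal costates `λ_E(T) = 1`, `λ_L(T) = 0`.  Since `H` has no explicit
`E`-dependence, `λ_E` is constant (= 1) wherever the floor `E ≥ E_min` is
inactive; off the floor

    dλ_L/dt = −λ_E · f_max·k_L/(L+k_L)² + m_L·λ_L.

The switching function is `σ = ∂H/∂u = α·λ_L − λ_E`: `σ > 0` forces `u` to
the ceiling, `σ < 0` forces `u = 0`, `σ ≡ 0` admits the singular arc, where
`dσ/dt = 0` pins `L = L*` above.  On an active floor arc the control is
interior, so `σ = 0` there too (`λ_L = λ_E/α`), and consistency of the two
adjoint equations yields the floor multiplier
`η = λ_E·(α·f_max·k_L/(L+k_L)² − m_L) ≥ 0` with `dλ_E/dt = −η`: the shadow
price of energy decays forward across the rationed-learning arc.
`estimate_costates` integrates this system backward (RK4) along the solved
trajectory, switching equation sets on the floor-activity mask;
`check_pmp` scores the bang-bang rule at mesh points, excluding
singular/floor points (`|σ| ≤ 0.01`, floor active) and a 2-point layer at
arc junctions, and passes at ≥ 95% consistency.

## Solver

Two stages, both deterministic given the seed:

1. **Direct collocation.**  Hermite–Simpson transcription on an `N`-interval
   mesh graded toward `t = 0` (node `k` at `T_max·(k/N)²`): the
   establishment/accumulation transient has a duration set by the reserves
   and rate constants, not by `T_max`, so long lifetimes need early
   resolution, while the exploitation tail is featureless.  States and
   control are nondimensionalised by problem scales (attainable energy,
   the knowledge fixed point, the control ceiling) so SLSQP sees O(1)
   quantities across the whole parameter box.  The floor is imposed at
   every node and Hermite midpoint; all Jacobians are analytic.  Initial
   guess: a linear ramp from ceiling to zero (plus seeded smooth
   perturbations for the multistart); defaults `N = 60`, one mesh-doubling
   refinement round, up to 3 starts.
2. **Arc polish (switching-time optimisation).**  A uniform-in-arc mesh
   quantises switch times, leaving an O(1/N) wobble on the objective
   (measured ~3·10⁻³ per doubling at N = 60) that no tractable mesh removes.
   The polish reads the arc sequence (ceiling / floor / singular / zero)
   off the converged NLP solution, replaces each arc by its exact feedback
   law — `u = ceiling` rolled off smoothly onto the floor law
   `u = intake − m + K·(E − E_min)` so energy approaches the floor from
   above and never undershoots; `u = m_L·L/α` to freeze knowledge on the
   singular arc; `u = 0` — and optimises the junction times (≤ 3 scalars)
   by Nelder–Mead (one restart) on a finely RK4-integrated terminal energy
   (1500 steps during search, 4000 for the final trajectory; numba-JIT
   when available).  The polish is **guarded**: it is kept only if it
   re-simulates at least as well as the raw NLP solution (tolerance
   10⁻³·max(1, |obj|)) and respects the floor to 10⁻⁶; otherwise the mesh
   solution stands.  With the polish, successive mesh rounds agree to
   ~10⁻⁶ and the refinement loop converges at its 10⁻⁴ criterion.

Failure is explicit: if SLSQP fails from every start, the returned
solution carries `converged = False` and diagnostics; nothing is silently
projected into feasibility.

## Dynamic-programming oracle

Backward value iteration on a (time × E × L) grid with a finite control
menu; one explicit-Euler step per stage per control and bilinear
interpolation of the next-stage value.  Default desk-scale grid: 200
stages, 80 × 80 states on `[E_min, E_min+10] × [0, 1.25·α·ceiling/m_L]`,
11 control levels — about one second at the baseline, agreeing with the
collocation objective to 0.3% (bar: 5%).  Falling below the floor is
"death", encoded as the finite value `E_min − 1`: strictly below every
live outcome (a live trajectory ends with `E ≥ E_min`), yet moderate, so
that a dead neighbour node cannot poison interpolated values of nearby
live states the way `−∞` (or any astronomical sentinel) does.  The greedy
rollout from `(E0, L0)` is the oracle's answer; it validates the solver
and is never the headline result.

## Phase classification

Point rules, first match wins (tolerances in brackets are the scale-free
defaults): establishment — `u ≥ ceiling − ε_u` and `E > E_min + ε_E`
[`ε_u = 0.01·ceiling`, `ε_E = 0.02·(E0 − E_min)`]; accumulation —
`E ≤ E_min + ε_E`; exploitation — `u ≤ ε_u`; maintenance —
`|α·u − m_L·L| ≤ ε_L` [`ε_L = 0.01·max(L)/T_max`], the derivative taken
from the rate law, never by differencing.  Unmatched (transition-layer)
points are absorbed into the nearer neighbouring segment; runs shorter
than `T_max/100` are merged forward; rule precedence resolves the moment
energy first touches the floor while investment is still at the ceiling
in favour of establishment.  Segment boundaries sit midway between
adjacent labelled mesh points and the segments partition `[0, T_max]`
exactly.  A residual out-of-order run (never observed on converged
solutions) is merged into its longer neighbour so the output always
satisfies the canonical-subsequence invariant.

One known tolerance collision: at extreme `k_L` (≈ 0.001) the singular
control `m_L·L*/α ≈ 0.009` falls below `ε_u`, so the (tiny-investment)
maintenance phase classifies as exploitation.  The scientific claims
tested there (no accumulation phase) are unaffected.

## Sweeps

`sweep_parameter` re-solves along one axis (`T_max`, `m_L`, `k_L`, `α`;
`m` is fixed, single published value) with the other constants at the
baseline: 16 cells spanning the published range, log-spaced for `k_L` and
`m_L`, linear otherwise.  Cells run at half the configured mesh with one
refinement round; a cell failing the Pontryagin check is re-solved at full
mesh; per-cell failures are recorded and the sweep continues.  Segment
times are divided by each cell's own lifetime (normalized age).  The trend
tests allow one adjacent-pair violation per sweep, absorbing single-cell
classification noise.

## Numerical choices and problem sizes

* Forward simulation: fixed-step RK4, default step `T_max/2000`
  (closed-form regression error < 10⁻⁶; step-halving changes the terminal
  energy by < 10⁻⁹).
* Default solve: mesh 60 → 120, ~10 s on one core including oracle-grade
  diagnostics; structure-only solves in property tests use mesh 24 without
  refinement (~2 s), and the box-wide order test covers 100 viable random
  parameter points at that setting.
* DP/NLP/polish are all deterministic for a fixed seed; CSV exports use
  15–17 significant digits so identical runs are byte-identical.
* Degenerate inputs: `T_max → 0` yields the initial state; `u_levels`
  menus that do not reach the ceiling warn (the DP value is then a lower
  bound for the restricted menu, useful for closed-form checks);
  infeasible trajectories are returned and *diagnosed*, never repaired,
  so the optimiser owns constraint enforcement.

## What the tests do and do not show

All quantitative checks run on this model's own synthetic dynamics — there
is no empirical data path.  Passing them shows that the solver, oracle,
adjoint diagnostics and classifier agree with each other and with closed
forms, and that the four-phase taxonomy and its parameter trends are
robust properties of the model across its published parameter box (where
a viable strategy exists).  They say nothing about how well the two-state
model describes any real organism or organisation.

## Known limitations

* Constant parameters over the lifetime; no stochasticity, no
  state-dependent intake ceiling, no re-dispersal (phase sequences never
  restart).
* The singular arc is validated through `|σ| ≤ tol`, not by a closed-form
  singular-control derivation; no global-optimality certificate beyond
  the DP cross-check.
* SLSQP's dense quadratic subproblems cap practical mesh sizes at a few
  hundred intervals; accuracy beyond that is delivered by the arc polish
  rather than the mesh.
* Non-viable parameter corners (negative sustainable net rate with long
  lifetimes) are genuinely infeasible problems: the solver reports
  failure rather than inventing a trajectory.
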