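# Methods

## Problem and model

The package plans casualty evacuation through a three-tier chain after a
mass-casualty earthquake.  Each disaster area `i` holds `q_is` casualties of
triage class `s` (serious or moderate, classified by a trauma-index score).
Road vehicles carry casualties to candidate temporary hospitals `j`;
after rapid stabilization, helicopters carry them onward to candidate
general hospitals `k`, which ends the episode.  The decision variables are
which hospitals to open, integer casualty flows per arc and class, and
integer tool counts per arc.

The objective is the urgency-weighted deterioration score accrued in
transit.  A class-`s` casualty deteriorates at `p_s` score points per hour
before treatment and at `0.2·p_s` afterwards; a leg with one-way travel
time `t` contributes `2·t·(rate)` per casualty (the factor 2 is kept exactly
as in the source formulation; it is consistent with tools making a round
trip).  Class weights `ω_s` express triage priority.  Money and treatment
time play no role: the model assumes stabilization is instantaneous relative
to transport and that every tool serves exactly one arc per wave.

Key structural constraints: demand coverage per (area, class); head-count
capacity `C` per temporary hospital (classes pooled); per-class capacity
`Q_ks` per general hospital; per-vehicle seat limits (`e_g = 6` road,
`e_h = 12` air); fleet totals; no dispatch from unopened hospitals; at
least one tool serving every opened hospital; flow conservation per
(temporary hospital, class).

## Formulations

The source formulation indexes a binary per (arc, vehicle), which is
hopelessly symmetric at realistic fleet sizes (hundreds of identical
vehicles).  The default **aggregated** formulation replaces these binaries
with one integer arc count `n_ij` (`m_jk` for the air leg), with
`Σ_s x_ijs ≤ e_g·n_ij`, arc non-emptiness `n_ij ≤ Σ_s x_ijs`, fleet totals
`Σ n_ij ≤ γ`, and opening constraints gated with the tight big-M `γ` (the
arc count can never exceed the fleet).  Because vehicles are identical and
the objective is linear in flows, the optimal objective is unchanged; the
test suite verifies this equivalence against the literal **per_vehicle**
formulation (with optional lexicographic symmetry-breaking) on batches of
small instances with fleets of at most 12.

Both formulations are held in a plain solver-agnostic container
(variables, linear constraints, objective) exportable as CPLEX LP text.
The bundled backend is HiGHS through `scipy.optimize.milp`, run at MIP gap
0 for all reported numbers; integer feasibility is HiGHS's default 1e-6.
Alternative optima can differ in routing, so tests assert objective values
and invariants (conservation, capacities, no flow through closed
hospitals), never specific routes.

## The embedded Lushan case

The 2013 Lushan earthquake case ships with the package: 9 disaster areas
(255 serious + 730 moderate casualties), 5 temporary-hospital candidates
(capacity 500 each), 3 general-hospital candidates with per-class
capacities, road times 0.45–2.45 h, air times 0.57–0.73 h, `ω = (2, 1)`,
`p = (0.8, 0.2)`, post-treatment factor 0.2.

One reading choice deserves note.  The case's published tabulation lists
150 road vehicles and 280 helicopters.  Under that reading the road fleet
can seat at most 150 × 6 = 900 casualties, fewer than the 985 the
constraints require to move in one wave — the case would admit no feasible
plan, contradicting the solutions published for it.  With the two
quantities transposed (280 vehicles, 150 helicopters) every published
setting is feasible and every published objective is reproduced to within
rounding.  The fixture therefore carries 280 vehicles and 150 helicopters.

## Robust counterpart

Casualty counts are interval-uncertain: `q ∈ [q̄ − q̂, q̄ + q̂]` with
`q̂ = δ·q̄` and a per-area protection budget `Γ ∈ [0, 1]`.  Because the
uncertainty enters only demand right-hand sides, the budgeted robust
counterpart collapses to demand inflation: coverage becomes
`Σ_j x ≥ q̄ + round(q̂·Γ)` (the dual variables of the protection function
are analytic intermediates and are never materialized).  An independent
worst-case oracle validates the collapse: for right-hand-side interval
uncertainty the adversary's optimum is the single extreme point
`q̄ + q̂·Γ` in every cell, so vertex enumeration reduces to evaluating that
one realization against a fixed plan.

Counts must be integers, so the protection term is rounded.  The default
rule is **ceiling** — the conservative choice (coverage never falls below
the continuous protection level), and the rule under which the package
reproduces the full published sensitivity grid on the Lushan case;
half-up and floor are available.  Rounding is applied to the deviation
term before adding the (integer) nominal.

Two useful exact properties follow from the construction and are enforced
by tests: the optimum depends on `(δ, Γ)` only through the product `δ·Γ`,
and it is monotone non-decreasing in each of `δ`, `Γ` and monotone
non-increasing in every capacity.

## Multi-period model

Time is discretized into `T` periods of length `Δt` hours (defaults:
`T = 2`, `Δt = 1`).  A casualty moved in period `t` has waited
`(t−1)·Δt` hours, so rates become `p_s((t−1)Δt + 2t_ij)` pre-treatment and
`0.2·p_s((t−1)Δt + 2t_jk)` post-treatment; at `t = 1` these reduce to the
static rates.  Tools are away for one period and then return; the
published availability recursion carries the per-tool seat count on both
sides, which cancels, leaving the constraint "seats used in two consecutive
periods ≤ fleet seat capacity".  Opening decisions are per period.
Temporary-hospital openings carry no cost term, so a solver may set an
opening variable with zero intake arbitrarily; solutions report openings
by positive intake (general hospitals are already forced closed when
unserved by their own constraint).

Under uncertainty the total coverage constraint inflates to
`q̄ + q̂·Γ′` while each period's draw from an area is capped at
`q̄ − q̂·Γ′` — both signs as published.  The asymmetric pair is satisfiable
only when `T ≥ 2` and `q̄ ≥ 3·round(q̂Γ′)` (for `T = 2`); the builder
rejects `T = 1` with a positive protection term, and tiny casualty counts
(single digits) can make the robust dynamic model structurally infeasible.
With ample fleet and no uncertainty the optimum moves everything in period
1 and coincides with the static model — the `T = 1` and `T = 2` nominal
limits are both tested.

## Benders decomposition

The decomposition splits along the two legs: the master holds road flows,
temporary openings and the vehicle fleet plus a surrogate `θ ≥ 0` for the
air-leg cost; the subproblem holds the air leg with the road totals per
(hospital, class, period) fixed.  The subproblem retains binary opening
variables, so no dual multipliers exist; the optimality cut is the
subproblem's value itself, `θ ≥ F2(x_trial)` — a constant.  Lower bounds
(master optima) are non-decreasing, upper bounds (incumbent
`F1 + F2`) non-increasing, and the loop stops at `UB − LB ≤ ε`
(`ε = 1e-6`, iteration cap 50); in practice it converges in two
iterations.  Infeasible subproblems (impossible on the shipped case, whose
general capacities dominate demand) trigger a no-good cut on the trial
opening pattern and a warning.

**Known limitation.** Because the cut carries no dependence on master
variables, the master can never trade a slightly worse road leg for a
cheaper air leg.  The decomposition's result equals the monolithic optimum
exactly when some road-optimal first stage is also jointly optimal — true
on the embedded case and most synthetic instances (air times are nearly
uniform, so the air-leg cost is insensitive to the road plan), but not
universally: on a minority of generated instances the decomposition
terminates with its internal gap closed yet 0.0002%–0.12% above the joint
optimum.  The monolithic solver is the correctness anchor; the test suite
asserts the equivalence and thereby documents exactly where the scheme's
constant cut falls short.

## Synthetic instances

The generator emulates the embedded case's structure at arbitrary size:
uniform integer casualty counts (default ranges 5–70 serious, 23–153
moderate, matching the case's spread), i.i.d. uniform travel times rounded
to 3 decimals (road 0.4–2.5 h, air 0.55–0.75 h), uniform temporary
capacity `C = ⌈1.2·total/|J|⌉`, per-class general capacities with the same
1.2 slack, and fleets sized at 1.3× the seat requirement (all slacks
configurable).  Realizations for stress tests are drawn independently and
uniformly on each cell's integer interval `[q̄ − q̂, q̄ + q̂]`; the
uncertainty set fixes only the support, and uniform sampling is this
package's documented choice, not a reproduction of any published sampling
law.  All draws flow through `numpy.random.default_rng(seed)`.

What the generator does **not** emulate: spatial correlation of travel
times, correlated casualty counts across areas, damaged-network effects,
or any within-tier routing.  Tests passing on synthetic instances
demonstrate model and algorithm correctness under the stated assumptions,
not predictive validity for real events.

Default sizes keep every test solve well under a second (9×5×3 like the
case, 3×2×2 with fleets ≤ 12 for per-vehicle fidelity checks); the largest
exercised size is 12×7×6.

## Experiment drivers

- **Sensitivity sweep**: one robust solve per (Γ, δ) grid cell; the Γ = 0
  row collapses to the single deterministic solve.
- **Feasibility stress test**: solves the deterministic and robust plans
  once, then evaluates each against seeded realizations, either by frozen
  flow coverage or (default) by re-solving transport restricted to the
  plan's opened hospitals — the restricted-recourse reading is used because
  whether replanning within opened facilities is allowed is otherwise
  unspecified.  Mean objectives are averaged over feasible samples only.
- **Capacity sweep**: re-solves across a grid of temporary capacities and
  general-capacity scale factors; infeasible cells are recorded, not
  raised.

## Degenerate inputs and numerical conventions

Zero demand yields an empty optimal plan (objective 0, nothing opened).
Validation rejects structural errors (missing matrix cells, negative
counts, overlapping id sets) and warns — without rejecting — when nominal
demand exceeds total capacity, since robust planning may be the caller's
next step.  Rates are computed in double precision; rounding happens only
in reporting.  The deviation-rounding guard band is 1e-9 (so 0.15·q·Γ
landing within 1e-9 of an integer is treated as that integer).  Extraction
cross-checks the recomputed objective split `F1 + F2` against the solver
objective at 1e-4 relative tolerance and fails loudly on disagreement.
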