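"""Computational study drivers: sensitivity sweeps, plan stress-testing and
capacity curves.

These reproduce the case study's experiment designs: a grid of robust solves
over (uncertainty budget, data variability); a Monte-Carlo comparison of the
deterministic and robust plans' feasibility under sampled demand
realizations; and objective-versus-capacity curves for both hospital tiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .instance import SEVERITIES, Instance
from .model import InfeasibleModelError, StaticSolution, solve_static
from .robust import UncertaintySpec, solve_robust
from .generate import perturb_realization


@dataclass
class SweepRow:
    gamma: float
    delta: float
    F1: float | None
    F2: float | None
    objective: float | None
    temp_open: tuple[str, ...]
    general_open: tuple[str, ...]
    status: str


@dataclass
class SweepResult:
    rows: list[SweepRow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "budget": r.gamma,
                    "variability": r.delta,
                    "trauma_index_pre": r.F1,
                    "trauma_index_post": r.F2,
                    "objective": r.objective,
                    "temp_hospitals": ",".join(r.temp_open),
                    "general_hospitals": ",".join(r.general_open),
                    "status": r.status,
                }
                for r in self.rows
            ]
        )

    def objective_at(self, gamma: float, delta: float) -> float | None:
        for r in self.rows:
            if r.gamma == gamma and r.delta == delta:
                return r.objective
        raise KeyError((gamma, delta))


def sensitivity_sweep(
    inst: Instance,
    gammas: list[float],
    deltas: list[float],
    rounding: str = "ceil",
    mip_gap: float = 0.0,
) -> SweepResult:
    """One robust solve per (budget, variability) cell.

    A zero budget makes every variability equivalent to the deterministic
    model, so it is solved once and recorded as a single row with
    ``delta = 0``.
    """
    rows: list[SweepRow] = []
    for gamma in sorted(set(gammas)):
        cell_deltas = [0.0] if gamma == 0 else sorted(set(deltas))
        for delta in cell_deltas:
            try:
                if gamma == 0:
                    sol = solve_static(inst, mip_gap=mip_gap)
                else:
                    sol = solve_robust(
                        inst,
                        UncertaintySpec(delta, gamma, rounding),
                        mip_gap=mip_gap,
                    )
                rows.append(
                    SweepRow(
                        gamma,
                        delta,
                        sol.F1,
                        sol.F2,
                        sol.objective,
                        tuple(sorted(sol.temp_open)),
                        tuple(sorted(sol.general_open)),
                        sol.solver_status.value,
                    )
                )
            except InfeasibleModelError as exc:
                rows.append(
                    SweepRow(gamma, delta, None, None, None, (), (), exc.status.value)
                )
    rows.sort(key=lambda r: (r.gamma, r.delta))
    return SweepResult(rows)


# ---------------------------------------------------------------------------
# Plan feasibility under sampled realizations


@dataclass
class FeasibilityRecord:
    gamma: float
    delta: float
    n_samples: int
    det_feasible: int
    rob_feasible: int
    det_mean_objective: float | None
    rob_mean_objective: float | None


def _plan_coverage(plan: StaticSolution, inst: Instance) -> dict[tuple[str, str], int]:
    return {
        (i, s): sum(plan.flows_road.get((i, j, s), 0) for j in inst.temp_candidates)
        for i in inst.areas
        for s in SEVERITIES
    }


def plan_feasible_frozen(
    plan: StaticSolution, inst: Instance, realized: dict[tuple[str, str], int]
) -> bool:
    """Frozen-flows check: the plan's arc flows must cover the realization."""
    cov = _plan_coverage(plan, inst)
    return all(cov[key] >= realized[key] for key in realized)


def plan_feasible_recourse(
    plan: StaticSolution, inst: Instance, realized: dict[tuple[str, str], int]
) -> tuple[bool, float | None]:
    """Restricted-recourse check: re-solve transport restricted to the plan's
    opened hospitals; the realization is feasible if a full routing exists.

    Returns (feasible, realized objective or None)."""
    restricted = _restrict_to_open(inst, plan)
    try:
        sol = solve_static(restricted, demand_rhs=realized, demand_sense="=")
    except InfeasibleModelError:
        return False, None
    return True, sol.objective


def _restrict_to_open(inst: Instance, plan: StaticSolution) -> Instance:
    caps = replace(inst.capacities)
    temp_cap = {
        j: (inst.capacities.temp_capacity[j] if j in plan.temp_open else 0)
        for j in inst.temp_candidates
    }
    gen_cap = {
        (k, s): (inst.capacities.general_capacity[(k, s)] if k in plan.general_open else 0)
        for k in inst.general_candidates
        for s in SEVERITIES
    }
    caps.temp_capacity = temp_cap
    caps.general_capacity = gen_cap
    return replace(inst, capacities=caps)


@dataclass
class FeasibilityResult:
    records: list[FeasibilityRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


def feasibility_experiment(
    inst: Instance,
    unc: UncertaintySpec,
    n_samples: int,
    seed: int,
    mode: str = "recourse",
) -> FeasibilityRecord:
    """Compare deterministic and robust plans on sampled demand realizations.

    Both plans are solved once; each of ``n_samples`` seeded realizations is
    then checked against each plan, either by re-solving a transport model
    restricted to the plan's opened hospitals (``mode="recourse"``, default)
    or by frozen-flow coverage (``mode="frozen"``).  Mean objectives are
    averaged over the feasible samples only.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if mode not in ("recourse", "frozen"):
        raise ValueError("mode must be 'recourse' or 'frozen'")
    det_plan = solve_static(inst)
    rob_plan = solve_robust(inst, unc)
    det_ok = rob_ok = 0
    det_obj: list[float] = []
    rob_obj: list[float] = []
    for n in range(n_samples):
        realized = dict(perturb_realization(inst, unc, seed + n).counts)
        for plan, ok_list, obj_list in (
            (det_plan, "det", det_obj),
            (rob_plan, "rob", rob_obj),
        ):
            if mode == "frozen":
                feasible = plan_feasible_frozen(plan, inst, realized)
                obj = plan.objective if feasible else None
            else:
                feasible, obj = plan_feasible_recourse(plan, inst, realized)
            if feasible:
                if ok_list == "det":
                    det_ok += 1
                else:
                    rob_ok += 1
                obj_list.append(obj)
    return FeasibilityRecord(
        gamma=unc.gamma(inst.areas[0]) if not isinstance(unc.budget, dict) else float("nan"),
        delta=unc.variability,
        n_samples=n_samples,
        det_feasible=det_ok,
        rob_feasible=rob_ok,
        det_mean_objective=(sum(det_obj) / len(det_obj)) if det_obj else None,
        rob_mean_objective=(sum(rob_obj) / len(rob_obj)) if rob_obj else None,
    )


# ---------------------------------------------------------------------------
# Capacity sweep


def capacity_sweep(
    inst: Instance,
    temp_caps: list[int],
    general_scales: list[float],
    unc: UncertaintySpec | None = None,
) -> pd.DataFrame:
    """Objective versus hospital capacity, one robust solve per grid cell.

    ``temp_caps`` replaces the uniform temporary capacity; ``general_scales``
    multiplies every general-hospital capacity.  Infeasible cells are
    recorded with a null objective.
    """
    rows = []
    for cap in temp_caps:
        for scale in general_scales:
            caps = replace(inst.capacities)
            caps.temp_capacity = {j: int(cap) for j in inst.temp_candidates}
            caps.general_capacity = {
                key: int(round(v * scale))
                for key, v in inst.capacities.general_capacity.items()
            }
            trial = replace(inst, capacities=caps)
            try:
                sol = (
                    solve_static(trial)
                    if unc is None
                    else solve_robust(trial, unc)
                )
                obj, status = sol.objective, sol.solver_status.value
            except InfeasibleModelError as exc:
                obj, status = None, exc.status.value
            rows.append(
                {
                    "temp_capacity": cap,
                    "general_scale": scale,
                    "objective": obj,
                    "status": status,
                }
            )
    return pd.DataFrame(rows)
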