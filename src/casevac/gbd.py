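"""Generalized Benders decomposition for the multi-period model.

The monolithic model splits along its two transport legs: the master
problem holds the road-leg flows, temporary-hospital openings and the
vehicle fleet, plus a surrogate ``theta`` for the air-leg cost; the
subproblem holds the air leg with the road-leg totals fixed.  Because the
subproblem keeps its binary opening variables, no dual multipliers are
available and the optimality cut is the subproblem's value itself:

    theta >= F2(x_trial)

a constant bound.  The cut carries no dependence on the master variables,
so the master cannot trade road-leg decisions against ``theta``; the loop
therefore converges in very few iterations (typically two), and its result
equals the monolithic optimum exactly when some road-leg-optimal plan is
also jointly optimal.  The monolithic solver in :mod:`casevac.dynamic` is
the correctness anchor for that equivalence and is asserted against in the
test suite.

If a trial first stage leaves the subproblem infeasible (possible only when
general-hospital capacity cannot absorb the routed totals), a no-good cut on
the trial road-leg totals is added and a warning logged.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

from .instance import SEVERITIES, Instance
from .model import CONTINUOUS, MILPModel, SolveStatus, solve_milp
from .model import _check_instance
from .dynamic import (
    DynamicSolution,
    PeriodSpec,
    _flag_degenerate_robust,
    add_first_stage,
    add_second_stage,
    extract_dynamic_solution,
)
from .robust import UncertaintySpec

log = logging.getLogger(__name__)


@dataclass
class GBDIteration:
    k: int
    lower_bound: float
    upper_bound: float
    theta: float
    sp_objective: float | None
    cut_added: bool


@dataclass
class GBDTrace:
    epsilon: float
    iterations: list[GBDIteration] = field(default_factory=list)
    converged: bool = False

    @property
    def final_gap(self) -> float:
        if not self.iterations:
            return math.inf
        last = self.iterations[-1]
        return last.upper_bound - last.lower_bound

    def to_dict(self) -> dict:
        return {
            "epsilon": self.epsilon,
            "converged": self.converged,
            "final_gap": self.final_gap,
            "iterations": [
                {
                    "k": it.k,
                    "lower_bound": it.lower_bound,
                    "upper_bound": it.upper_bound,
                    "theta": it.theta,
                    "sp_objective": it.sp_objective,
                    "cut_added": it.cut_added,
                }
                for it in self.iterations
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "GBDTrace":
        trace = cls(epsilon=d["epsilon"], converged=d["converged"])
        trace.iterations = [
            GBDIteration(
                k=r["k"],
                lower_bound=r["lower_bound"],
                upper_bound=r["upper_bound"],
                theta=r["theta"],
                sp_objective=r["sp_objective"],
                cut_added=r["cut_added"],
            )
            for d_r in [d["iterations"]]
            for r in d_r
        ]
        return trace

    def to_csv(self) -> str:
        lines = ["k,lower_bound,upper_bound,gap"]
        for it in self.iterations:
            lines.append(
                f"{it.k},{it.lower_bound!r},{it.upper_bound!r},"
                f"{it.upper_bound - it.lower_bound!r}"
            )
        return "\n".join(lines) + "\n"


def build_master(
    inst: Instance, periods: PeriodSpec, unc: UncertaintySpec | None = None
) -> MILPModel:
    """Road-leg master problem with the air-leg surrogate ``theta``."""
    _check_instance(inst)
    _flag_degenerate_robust(inst, periods, unc)
    m = MILPModel(tag=f"gbd_master/T={periods.n_periods}")
    add_first_stage(m, inst, periods, unc)
    m.add_var("theta", lower=0.0, domain=CONTINUOUS, obj=1.0)
    return m


def build_subproblem(
    x_totals: dict[tuple[str, str, int], int],
    inst: Instance,
    periods: PeriodSpec,
) -> MILPModel:
    """Air-leg subproblem with road-leg totals per (j, s, t) held fixed."""
    m = MILPModel(tag=f"gbd_subproblem/T={periods.n_periods}")
    add_second_stage(m, inst, periods, fixed_x_totals=x_totals)
    return m


def _road_totals(
    raw_values: dict[str, float], inst: Instance, periods: PeriodSpec
) -> dict[tuple[str, str, int], int]:
    totals: dict[tuple[str, str, int], int] = {}
    for j in inst.temp_candidates:
        for s in SEVERITIES:
            for t in periods.periods:
                tot = sum(
                    int(round(raw_values.get(f"x[{i},{j},{s},{t}]", 0.0)))
                    for i in inst.areas
                )
                totals[(j, s, t)] = tot
    return totals


def gbd_solve(
    inst: Instance,
    periods: PeriodSpec,
    unc: UncertaintySpec | None = None,
    epsilon: float = 1e-6,
    max_iterations: int = 50,
    mip_gap: float = 0.0,
) -> tuple[DynamicSolution | None, GBDTrace]:
    """Run the decomposition loop; returns the incumbent and the full trace."""
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    master = build_master(inst, periods, unc)
    trace = GBDTrace(epsilon=epsilon)
    upper = math.inf
    incumbent_values: dict[str, float] | None = None

    for k in range(1, max_iterations + 1):
        mp = solve_milp(master, mip_gap=mip_gap)
        if mp.status is not SolveStatus.OPTIMAL:
            log.warning("master problem not optimal (status %s); aborting", mp.status.value)
            break
        lower = mp.objective  # F1(x) + theta
        theta = mp.values["theta"]
        f1_trial = lower - theta

        totals = _road_totals(mp.values, inst, periods)
        sp = solve_milp(build_subproblem(totals, inst, periods), mip_gap=mip_gap)
        cut_added = False
        if sp.status is SolveStatus.OPTIMAL:
            trial_ub = f1_trial + sp.objective
            if trial_ub < upper - 1e-12:
                upper = trial_ub
                incumbent_values = dict(mp.values)
                incumbent_values.update(sp.values)
            if upper - lower <= epsilon:
                trace.iterations.append(
                    GBDIteration(k, lower, upper, theta, sp.objective, False)
                )
                trace.converged = True
                break
            master.add_constr(f"cut[{k}]", {"theta": 1.0}, ">=", sp.objective)
            cut_added = True
            trace.iterations.append(
                GBDIteration(k, lower, upper, theta, sp.objective, cut_added)
            )
        else:
            # no-good cut on the trial road-leg totals: at least one (j,s,t)
            # total must change (the published scheme gives no feasibility cut)
            log.warning(
                "subproblem infeasible at iteration %d; adding no-good cut on "
                "the trial opening pattern",
                k,
            )
            _add_no_good_cut(master, mp.values, inst, periods, k)
            trace.iterations.append(GBDIteration(k, lower, upper, theta, None, True))
    solution = None
    if incumbent_values is not None:
        raw = _assemble_raw(incumbent_values, upper)
        solution = extract_dynamic_solution(raw, inst, periods)
    return solution, trace


def _assemble_raw(values: dict[str, float], objective: float):
    from .model import RawSolution

    return RawSolution(status=SolveStatus.OPTIMAL, objective=objective, values=values)


def _add_no_good_cut(
    master: MILPModel,
    trial_values: dict[str, float],
    inst: Instance,
    periods: PeriodSpec,
    k: int,
) -> None:
    """Exclude the trial temporary-hospital opening pattern."""
    coeffs: dict[str, float] = {}
    rhs = 1.0
    for j in inst.temp_candidates:
        for t in periods.periods:
            name = f"U[{j},{t}]"
            if trial_values.get(name, 0.0) > 0.5:
                coeffs[name] = -1.0
                rhs -= 1.0
            else:
                coeffs[name] = 1.0
    master.add_constr(f"ng_cut[{k}]", coeffs, ">=", rhs)
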