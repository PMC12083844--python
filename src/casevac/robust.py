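"""Budget-of-uncertainty robust counterpart for uncertain casualty counts.

Each nominal count ``q`` carries a symmetric deviation ``q_hat = delta * q``
(``delta`` is the data-variability fraction) and a per-area budget
``Gamma in [0, 1]`` scaling how much of the deviation the plan must absorb.
With uncertainty confined to demand right-hand sides, the robust counterpart
collapses to demand inflation: each coverage constraint becomes
``sum_j x >= q + round(q_hat * Gamma)`` where ``round`` is an integer
rounding rule.

The default rule is ``ceil``: rounding the protection term up is the
conservative choice (the plan always covers at least the continuous
protection level) and is the rule under which the package reproduces the
published Lushan sensitivity table.  ``half_up`` and ``floor`` are provided
as alternatives.

``worst_case_oracle`` validates the collapse independently: because the
uncertainty is interval-wise on right-hand sides only, the protection
function is maximized at the single extreme point ``q + q_hat * Gamma``, so
exhaustive vertex enumeration reduces to evaluating that one realization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .instance import SEVERITIES, Instance
from .model import (
    MILPModel,
    StaticSolution,
    build_static,
    solve_static,
)

ROUNDINGS = ("ceil", "half_up", "floor")
# guard against 0.15 * q * Gamma landing epsilon above an integer
_EPS = 1e-9


def _round(value: float, rule: str) -> int:
    if rule == "ceil":
        return math.ceil(value - _EPS)
    if rule == "floor":
        return math.floor(value + _EPS)
    if rule == "half_up":
        return math.floor(value + 0.5 + _EPS)
    raise ValueError(f"unknown rounding rule {rule!r}; choose from {ROUNDINGS}")


@dataclass
class UncertaintySpec:
    """Variability fraction, per-area budgets and the deviation rounding rule.

    ``budget`` may be a scalar (broadcast to every area) or a map
    area -> Gamma.
    """

    variability: float
    budget: float | Mapping[str, float] = 1.0
    rounding: str = "ceil"

    def __post_init__(self) -> None:
        if not 0 <= self.variability <= 1:
            raise ValueError("variability must lie in [0, 1]")
        if self.rounding not in ROUNDINGS:
            raise ValueError(f"unknown rounding rule {self.rounding!r}")
        gammas = (
            self.budget.values() if isinstance(self.budget, Mapping) else [self.budget]
        )
        for g in gammas:
            if not 0 <= g <= 1:
                raise ValueError("budget values must lie in [0, 1]")

    def gamma(self, area: str) -> float:
        if isinstance(self.budget, Mapping):
            return self.budget[area]
        return float(self.budget)

    def deviation(self, q_nominal: int) -> int:
        """Integer maximum deviation q_hat for a nominal count."""
        return _round(self.variability * q_nominal, self.rounding)


def inflated_demand(
    q_nominal: int, delta: float, gamma: float, rounding: str = "ceil"
) -> int:
    """Protected demand level ``q + round(delta * q * Gamma)``."""
    if q_nominal < 0:
        raise ValueError("nominal count must be non-negative")
    if not 0 <= delta <= 1:
        raise ValueError("variability must lie in [0, 1]")
    if not 0 <= gamma <= 1:
        raise ValueError("budget must lie in [0, 1]")
    return q_nominal + _round(delta * q_nominal * gamma, rounding)


def inflated_demand_table(
    inst: Instance, unc: UncertaintySpec
) -> dict[tuple[str, str], int]:
    return {
        (i, s): inflated_demand(
            inst.casualties.get(i, s), unc.variability, unc.gamma(i), unc.rounding
        )
        for i in inst.areas
        for s in SEVERITIES
    }


def build_robust(
    inst: Instance, unc: UncertaintySpec, formulation: str = "aggregated"
) -> MILPModel:
    """Robust counterpart: the static model with inflated ``>=`` demands."""
    model = build_static(
        inst,
        demand_rhs=inflated_demand_table(inst, unc),
        formulation=formulation,
        demand_sense=">=",
    )
    model.tag = f"robust/{formulation}"
    return model


def solve_robust(
    inst: Instance,
    unc: UncertaintySpec,
    formulation: str = "aggregated",
    mip_gap: float = 0.0,
    time_limit: float | None = None,
) -> StaticSolution:
    return solve_static(
        inst,
        demand_rhs=inflated_demand_table(inst, unc),
        formulation=formulation,
        demand_sense=">=",
        mip_gap=mip_gap,
        time_limit=time_limit,
    )


@dataclass
class WorstCaseReport:
    feasible: bool
    worst_objective: float | None
    shortfalls: dict[tuple[str, str], int] = field(default_factory=dict)


def worst_case_oracle(
    inst: Instance, unc: UncertaintySpec, plan: StaticSolution
) -> WorstCaseReport:
    """Evaluate a fixed plan against the worst demand realization.

    For right-hand-side interval uncertainty the adversary's optimum is the
    extreme point ``q + q_hat * Gamma`` in every (area, severity) cell
    simultaneously; the oracle checks whether the plan's arc flows cover that
    realization and reports the plan's realized objective (the plan's flows
    are fixed, so its accrued score is its own objective whenever feasible).
    """
    worst = inflated_demand_table(inst, unc)
    shortfalls: dict[tuple[str, str], int] = {}
    for i in inst.areas:
        for s in SEVERITIES:
            covered = sum(
                plan.flows_road.get((i, j, s), 0) for j in inst.temp_candidates
            )
            if covered < worst[(i, s)]:
                shortfalls[(i, s)] = worst[(i, s)] - covered
    feasible = not shortfalls
    return WorstCaseReport(
        feasible=feasible,
        worst_objective=plan.objective if feasible else None,
        shortfalls=shortfalls,
    )
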