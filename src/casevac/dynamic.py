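"""Two-stage / multi-period dynamic location-transportation model.

Time is discretized into ``T`` periods of length ``dt`` hours.  Casualties
moved in later periods have waited, so per-casualty deterioration grows with
the period index (see :mod:`casevac.rates`).  Rescue tools used in period
``t`` are away for that period and return at ``t + 1``; the fleet
availability recursion is

    avail[1] = total
    avail[t+1] = avail[t] - usage[t] + usage[t-1]          (usage[0] = 0)

which telescopes to ``avail[t+1] = total - usage[t]``: the model simply
caps consecutive-period usage at the fleet's seat capacity.  The published
recursion carries the per-tool seat count on both sides; it cancels, and the
model applies the constraint in casualty units.

Under demand uncertainty with per-area budget ``Gamma'`` the total coverage
constraint inflates to ``q + q_hat * Gamma'`` while the per-period draw is
capped at ``q - q_hat * Gamma'`` (both signs as published); with a positive
protection term this pair is satisfiable only for ``T >= 2``, and the
builder flags the ``T = 1`` case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .instance import SEVERITIES, Instance
from .model import (
    BINARY,
    INTEGER,
    InfeasibleModelError,
    MILPModel,
    RawSolution,
    SolveStatus,
    solve_milp,
)
from .model import _check_instance
from .rates import dynamic_post_rate, dynamic_pre_rate
from .robust import UncertaintySpec, _round


@dataclass
class PeriodSpec:
    n_periods: int = 2
    period_length: float = 1.0  # hours

    def __post_init__(self) -> None:
        if self.n_periods < 1:
            raise ValueError("n_periods must be >= 1")
        if self.period_length <= 0:
            raise ValueError("period_length must be positive")

    @property
    def periods(self) -> range:
        return range(1, self.n_periods + 1)


@dataclass
class DynamicSolution:
    temp_open: dict[int, set[str]]
    general_open: dict[int, set[str]]
    flows_road: dict[tuple[str, str, str, int], int]
    flows_air: dict[tuple[str, str, str, int], int]
    vehicle_avail: list[int]
    helicopter_avail: list[int]
    F1: float
    F2: float
    objective: float
    solver_status: SolveStatus

    def to_dict(self) -> dict:
        return {
            "temp_open": {t: sorted(v) for t, v in self.temp_open.items()},
            "general_open": {t: sorted(v) for t, v in self.general_open.items()},
            "flows_road": [
                {"from": i, "to": j, "severity": s, "period": t, "count": c}
                for (i, j, s, t), c in sorted(self.flows_road.items())
                if c > 0
            ],
            "flows_air": [
                {"from": j, "to": k, "severity": s, "period": t, "count": c}
                for (j, k, s, t), c in sorted(self.flows_air.items())
                if c > 0
            ],
            "vehicle_avail": self.vehicle_avail,
            "helicopter_avail": self.helicopter_avail,
            "F1": self.F1,
            "F2": self.F2,
            "objective": self.objective,
            "solver_status": self.solver_status.value,
        }


def fleet_availability(total: int, usage: list[int]) -> list[int]:
    """Tool availability per period under the return-after-one-period rule.

    Returns ``len(usage) + 1`` entries (availability before each period and
    after the last).  Raises if any period's usage exceeds its availability.
    """
    avail = [total]
    prev_usage = 0
    for t, used in enumerate(usage, start=1):
        if used > avail[-1]:
            raise ValueError(
                f"period {t} uses {used} tools but only {avail[-1]} are available"
            )
        avail.append(avail[-1] - used + prev_usage)
        prev_usage = used
    return avail


def _protection(inst: Instance, unc: UncertaintySpec | None) -> dict[tuple[str, str], int]:
    if unc is None:
        return {(i, s): 0 for i in inst.areas for s in SEVERITIES}
    return {
        (i, s): _round(
            unc.variability * inst.casualties.get(i, s) * unc.gamma(i), unc.rounding
        )
        for i in inst.areas
        for s in SEVERITIES
    }


def add_first_stage(
    m: MILPModel,
    inst: Instance,
    periods: PeriodSpec,
    unc: UncertaintySpec | None = None,
) -> None:
    """Road-leg variables and constraints (flows x, openings U, vehicle fleet)."""
    I, J = inst.areas, inst.temp_candidates
    eg, gamma = inst.fleet.vehicle_capacity, inst.fleet.n_vehicles
    dt = periods.period_length
    prot = _protection(inst, unc)

    for t in periods.periods:
        for j in J:
            m.add_var(f"U[{j},{t}]", domain=BINARY)
        for i in I:
            for j in J:
                for s in SEVERITIES:
                    coef = (
                        dynamic_pre_rate(
                            inst.times.road_hours[(i, j)], inst.severity(s), t, dt
                        )
                        * inst.severity(s).urgency_weight
                    )
                    m.add_var(f"x[{i},{j},{s},{t}]", domain=INTEGER, obj=coef)

    for t in periods.periods:
        # period intake gated by the period's opening decision
        for j in J:
            coeffs = {f"x[{i},{j},{s},{t}]": 1.0 for i in I for s in SEVERITIES}
            coeffs[f"U[{j},{t}]"] = -float(inst.temp_cap(j))
            m.add_constr(f"temp_gate[{j},{t}]", coeffs, "<=", 0.0)
        # vehicle seats over two consecutive periods (tools return after one)
        coeffs = {f"x[{i},{j},{s},{t}]": 1.0 for i in I for j in J for s in SEVERITIES}
        if t > 1:
            coeffs.update(
                {f"x[{i},{j},{s},{t - 1}]": 1.0 for i in I for j in J for s in SEVERITIES}
            )
        m.add_constr(f"veh_seats[{t}]", coeffs, "<=", float(eg * gamma))
        # per-period draw cap
        for i in I:
            for s in SEVERITIES:
                q = inst.casualties.get(i, s)
                m.add_constr(
                    f"period_cap[{i},{s},{t}]",
                    {f"x[{i},{j},{s},{t}]": 1.0 for j in J},
                    "<=",
                    q - prot[(i, s)],
                )
    # cumulative temporary capacity
    for j in J:
        m.add_constr(
            f"temp_cap_total[{j}]",
            {
                f"x[{i},{j},{s},{t}]": 1.0
                for i in I
                for s in SEVERITIES
                for t in periods.periods
            },
            "<=",
            inst.temp_cap(j),
        )
    # total coverage (inflated when robust)
    for i in I:
        for s in SEVERITIES:
            q = inst.casualties.get(i, s)
            sense, rhs = ("=", float(q)) if unc is None else (">=", float(q + prot[(i, s)]))
            m.add_constr(
                f"coverage[{i},{s}]",
                {f"x[{i},{j},{s},{t}]": 1.0 for j in J for t in periods.periods},
                sense,
                rhs,
            )


def add_second_stage(
    m: MILPModel,
    inst: Instance,
    periods: PeriodSpec,
    fixed_x_totals: Mapping[tuple[str, str, int], int] | None = None,
) -> None:
    """Air-leg variables and constraints (flows y, openings V, helicopters).

    When ``fixed_x_totals`` is given (Benders subproblem), flow conservation
    uses those totals as constants; otherwise it links to the first-stage x
    variables assumed present in the model.
    """
    I, J, K = inst.areas, inst.temp_candidates, inst.general_candidates
    eh, lam = inst.fleet.helicopter_capacity, inst.fleet.n_helicopters
    dt = periods.period_length
    f = inst.post_treatment_factor

    for t in periods.periods:
        for k in K:
            m.add_var(f"V[{k},{t}]", domain=BINARY)
        for j in J:
            for k in K:
                for s in SEVERITIES:
                    coef = (
                        dynamic_post_rate(
                            inst.times.air_hours[(j, k)], inst.severity(s), t, dt, f
                        )
                        * inst.severity(s).urgency_weight
                    )
                    m.add_var(f"y[{j},{k},{s},{t}]", domain=INTEGER, obj=coef)

    for t in periods.periods:
        for k in K:
            for s in SEVERITIES:
                coeffs = {f"y[{j},{k},{s},{t}]": 1.0 for j in J}
                coeffs[f"V[{k},{t}]"] = -float(inst.general_cap(k, s))
                m.add_constr(f"gen_gate[{k},{s},{t}]", coeffs, "<=", 0.0)
            served = {f"y[{j},{k},{s},{t}]": 1.0 for j in J for s in SEVERITIES}
            served[f"V[{k},{t}]"] = -1.0
            m.add_constr(f"open_served[{k},{t}]", served, ">=", 0.0)
        coeffs = {f"y[{j},{k},{s},{t}]": 1.0 for j in J for k in K for s in SEVERITIES}
        if t > 1:
            coeffs.update(
                {f"y[{j},{k},{s},{t - 1}]": 1.0 for j in J for k in K for s in SEVERITIES}
            )
        m.add_constr(f"heli_seats[{t}]", coeffs, "<=", float(eh * lam))
        for j in J:
            for s in SEVERITIES:
                coeffs = {f"y[{j},{k},{s},{t}]": 1.0 for k in K}
                if fixed_x_totals is None:
                    coeffs.update({f"x[{i},{j},{s},{t}]": -1.0 for i in I})
                    m.add_constr(f"conserve[{j},{s},{t}]", coeffs, "=", 0.0)
                else:
                    m.add_constr(
                        f"conserve[{j},{s},{t}]",
                        coeffs,
                        "=",
                        float(fixed_x_totals.get((j, s, t), 0)),
                    )
    for k in K:
        for s in SEVERITIES:
            m.add_constr(
                f"gen_cap_total[{k},{s}]",
                {
                    f"y[{j},{k},{s},{t}]": 1.0
                    for j in J
                    for t in periods.periods
                },
                "<=",
                inst.general_cap(k, s),
            )


def build_two_stage(
    inst: Instance,
    periods: PeriodSpec,
    unc: UncertaintySpec | None = None,
) -> MILPModel:
    """Monolithic multi-period MILP (both legs solved jointly)."""
    _check_instance(inst)
    _flag_degenerate_robust(inst, periods, unc)
    m = MILPModel(tag=f"two_stage/T={periods.n_periods}")
    add_first_stage(m, inst, periods, unc)
    add_second_stage(m, inst, periods)
    return m


def _flag_degenerate_robust(
    inst: Instance, periods: PeriodSpec, unc: UncertaintySpec | None
) -> None:
    if unc is None or periods.n_periods > 1:
        return
    prot = _protection(inst, unc)
    if any(v > 0 for v in prot.values()):
        raise InfeasibleModelError(
            "robust multi-period model with a positive protection term requires "
            "T >= 2: total coverage must exceed the nominal count while every "
            "period is capped below it",
            SolveStatus.INFEASIBLE,
        )


def extract_dynamic_solution(raw: RawSolution, inst: Instance, periods: PeriodSpec) -> DynamicSolution:
    if raw.status is not SolveStatus.OPTIMAL:
        raise ValueError(f"cannot extract from non-optimal solve (status {raw.status.value})")
    I, J, K = inst.areas, inst.temp_candidates, inst.general_candidates
    dt = periods.period_length
    f = inst.post_treatment_factor

    flows_road: dict[tuple[str, str, str, int], int] = {}
    flows_air: dict[tuple[str, str, str, int], int] = {}
    for name, v in raw.values.items():
        if v <= 1e-6:
            continue
        if name.startswith("x["):
            i, j, s, t = name[2:-1].split(",")
            flows_road[(i, j, s, int(t))] = int(round(v))
        elif name.startswith("y["):
            j, k, s, t = name[2:-1].split(",")
            flows_air[(j, k, s, int(t))] = int(round(v))

    F1 = sum(
        dynamic_pre_rate(inst.times.road_hours[(i, j)], inst.severity(s), t, dt)
        * inst.severity(s).urgency_weight
        * c
        for (i, j, s, t), c in flows_road.items()
    )
    F2 = sum(
        dynamic_post_rate(inst.times.air_hours[(j, k)], inst.severity(s), t, dt, f)
        * inst.severity(s).urgency_weight
        * c
        for (j, k, s, t), c in flows_air.items()
    )
    # openings are reported by activity: an opening variable with zero intake
    # is cost-free to the solver and carries no information
    temp_open = {
        t: {
            j
            for j in J
            if any(flows_road.get((i, j, s, t), 0) > 0 for i in I for s in SEVERITIES)
        }
        for t in periods.periods
    }
    general_open = {
        t: {
            k
            for k in K
            if any(flows_air.get((j, k, s, t), 0) > 0 for j in J for s in SEVERITIES)
        }
        for t in periods.periods
    }
    veh_usage = [
        -(-sum(c for (_, _, _, t2), c in flows_road.items() if t2 == t) // inst.fleet.vehicle_capacity)
        for t in periods.periods
    ]
    heli_usage = [
        -(-sum(c for (_, _, _, t2), c in flows_air.items() if t2 == t) // inst.fleet.helicopter_capacity)
        for t in periods.periods
    ]
    return DynamicSolution(
        temp_open=temp_open,
        general_open=general_open,
        flows_road=flows_road,
        flows_air=flows_air,
        vehicle_avail=fleet_availability(inst.fleet.n_vehicles, veh_usage),
        helicopter_avail=fleet_availability(inst.fleet.n_helicopters, heli_usage),
        F1=F1,
        F2=F2,
        objective=F1 + F2,
        solver_status=raw.status,
    )


def solve_two_stage(
    inst: Instance,
    periods: PeriodSpec,
    unc: UncertaintySpec | None = None,
    mip_gap: float = 0.0,
    time_limit: float | None = None,
) -> DynamicSolution:
    model = build_two_stage(inst, periods, unc)
    raw = solve_milp(model, mip_gap=mip_gap, time_limit=time_limit)
    if raw.status is not SolveStatus.OPTIMAL:
        raise InfeasibleModelError(
            f"two-stage model not solved to optimality (status {raw.status.value})",
            raw.status,
        )
    return extract_dynamic_solution(raw, inst, periods)
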