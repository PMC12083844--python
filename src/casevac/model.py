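"""Solver-agnostic MILP container, the HiGHS backend, and the static model.

The static model opens temporary and general hospitals and routes every
casualty area -> temporary -> general so that the urgency-weighted total
deterioration score is minimal, subject to hospital capacities, per-vehicle
seat limits and fleet sizes.

Two interchangeable formulations are provided:

``aggregated`` (default)
    Integer arc counts ``n[i,j]`` / ``m[j,k]`` replace the per-vehicle
    assignment binaries.  Because vehicles are identical and the objective
    is linear in flows, the optimal objective is unchanged; the model is
    dramatically smaller and free of index symmetry.

``per_vehicle``
    The literal formulation with one binary per (arc, vehicle).  Intended
    for fidelity checks at small fleet sizes; optional symmetry-breaking
    ordering constraints keep it tractable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint
from scipy.optimize import milp as _scipy_milp

from .instance import SEVERITIES, Instance, validate
from .rates import objective_terms

CONTINUOUS = "continuous"
INTEGER = "integer"
BINARY = "binary"


@dataclass
class Variable:
    name: str
    lower: float = 0.0
    upper: float = math.inf
    domain: str = CONTINUOUS


@dataclass
class Constraint:
    name: str
    coeffs: dict[str, float]
    sense: str  # "<=", "=", ">="
    rhs: float


@dataclass
class MILPModel:
    """A plain linear model: variables, linear constraints, min objective."""

    tag: str = "model"
    variables: list[Variable] = field(default_factory=list)
    constraints: list[Constraint] = field(default_factory=list)
    objective: dict[str, float] = field(default_factory=dict)
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def add_var(
        self,
        name: str,
        lower: float = 0.0,
        upper: float = math.inf,
        domain: str = CONTINUOUS,
        obj: float = 0.0,
    ) -> str:
        if name in self._index:
            raise ValueError(f"duplicate variable {name!r}")
        self._index[name] = len(self.variables)
        self.variables.append(Variable(name, lower, upper, domain))
        if obj:
            self.objective[name] = obj
        return name

    def add_constr(
        self, name: str, coeffs: Mapping[str, float], sense: str, rhs: float
    ) -> None:
        if sense not in ("<=", "=", ">="):
            raise ValueError(f"bad constraint sense {sense!r}")
        for v in coeffs:
            if v not in self._index:
                raise ValueError(f"constraint {name!r} references unknown variable {v!r}")
        self.constraints.append(Constraint(name, dict(coeffs), sense, float(rhs)))

    @property
    def n_vars(self) -> int:
        return len(self.variables)

    def var_index(self, name: str) -> int:
        return self._index[name]

    # -- export -------------------------------------------------------------

    def to_lp(self) -> str:
        """Render in CPLEX LP text format."""

        def term(c: float, v: str) -> str:
            sign = "+" if c >= 0 else "-"
            return f" {sign} {abs(c):.12g} {v}"

        lines = ["Minimize", " obj:" + "".join(term(c, v) for v, c in self.objective.items())]
        lines.append("Subject To")
        op = {"<=": "<=", ">=": ">=", "=": "="}
        for con in self.constraints:
            expr = "".join(term(c, v) for v, c in con.coeffs.items() if c != 0)
            lines.append(f" {con.name}:{expr} {op[con.sense]} {con.rhs:.12g}")
        bounds, generals, binaries = [], [], []
        for v in self.variables:
            if v.domain == BINARY:
                binaries.append(v.name)
                continue
            if v.domain == INTEGER:
                generals.append(v.name)
            lo = f"{v.lower:.12g}" if math.isfinite(v.lower) else "-inf"
            hi = f"{v.upper:.12g}" if math.isfinite(v.upper) else "+inf"
            if not (v.lower == 0 and math.isinf(v.upper)):
                bounds.append(f" {lo} <= {v.name} <= {hi}")
        if bounds:
            lines.append("Bounds")
            lines.extend(bounds)
        if generals:
            lines.append("Generals")
            lines.append(" " + " ".join(generals))
        if binaries:
            lines.append("Binaries")
            lines.append(" " + " ".join(binaries))
        lines.append("End")
        return "\n".join(lines) + "\n"


class SolveStatus(str, Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    UNBOUNDED = "unbounded"
    LIMIT = "limit"
    ERROR = "error"


@dataclass
class RawSolution:
    status: SolveStatus
    objective: float | None
    values: dict[str, float]
    mip_gap: float | None = None
    message: str = ""

    def value(self, name: str) -> float:
        return self.values[name]


_STATUS_MAP = {0: SolveStatus.OPTIMAL, 1: SolveStatus.LIMIT, 2: SolveStatus.INFEASIBLE,
               3: SolveStatus.UNBOUNDED, 4: SolveStatus.ERROR}


def solve_milp(
    model: MILPModel,
    mip_gap: float = 0.0,
    time_limit: float | None = None,
    presolve: bool = True,
) -> RawSolution:
    """Solve with the bundled HiGHS backend (``scipy.optimize.milp``)."""
    n = model.n_vars
    c = np.zeros(n)
    for v, coef in model.objective.items():
        c[model.var_index(v)] = coef

    rows, cols, vals = [], [], []
    lb_con = np.empty(len(model.constraints))
    ub_con = np.empty(len(model.constraints))
    for r, con in enumerate(model.constraints):
        for v, coef in con.coeffs.items():
            rows.append(r)
            cols.append(model.var_index(v))
            vals.append(coef)
        if con.sense == "<=":
            lb_con[r], ub_con[r] = -np.inf, con.rhs
        elif con.sense == ">=":
            lb_con[r], ub_con[r] = con.rhs, np.inf
        else:
            lb_con[r] = ub_con[r] = con.rhs
    A = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(model.constraints), n)
    )

    lb = np.array([v.lower for v in model.variables], dtype=float)
    ub = np.array([v.upper for v in model.variables], dtype=float)
    integrality = np.array(
        [0 if v.domain == CONTINUOUS else 1 for v in model.variables]
    )
    for idx, v in enumerate(model.variables):
        if v.domain == BINARY:
            lb[idx], ub[idx] = max(lb[idx], 0.0), min(ub[idx], 1.0)

    options: dict = {"mip_rel_gap": mip_gap, "presolve": presolve}
    if time_limit is not None:
        options["time_limit"] = time_limit
    res = _scipy_milp(
        c,
        constraints=LinearConstraint(A, lb_con, ub_con),
        integrality=integrality,
        bounds=Bounds(lb, ub),
        options=options,
    )
    status = _STATUS_MAP.get(res.status, SolveStatus.ERROR)
    values = (
        {v.name: float(res.x[i]) for i, v in enumerate(model.variables)}
        if res.x is not None
        else {}
    )
    return RawSolution(
        status=status,
        objective=float(res.fun) if res.fun is not None else None,
        values=values,
        mip_gap=float(res.mip_gap) if getattr(res, "mip_gap", None) is not None else None,
        message=str(res.message),
    )


# ---------------------------------------------------------------------------
# Static model builders


def vehicles_required(arc_flow: int, capacity: int) -> int:
    """Minimum identical vehicles needed to carry ``arc_flow`` casualties."""
    if capacity < 1:
        raise ValueError("vehicle capacity must be >= 1")
    if arc_flow < 0:
        raise ValueError("arc flow must be non-negative")
    return -(-arc_flow // capacity)


def _check_instance(inst: Instance) -> None:
    rep = validate(inst)
    if not rep.ok:
        raise ValueError("invalid instance: " + "; ".join(m for _, m in rep.errors))


def build_static(
    inst: Instance,
    demand_rhs: Mapping[tuple[str, str], int] | None = None,
    formulation: str = "aggregated",
    demand_sense: str = "=",
    symmetry_break: bool = True,
) -> MILPModel:
    """Build the single-period location-allocation MILP.

    ``demand_rhs`` defaults to the nominal casualty counts; the robust
    counterpart passes inflated demands with ``demand_sense=">="``.
    """
    _check_instance(inst)
    if demand_rhs is None:
        demand_rhs = inst.nominal_demand()
    if demand_sense not in ("=", ">="):
        raise ValueError("demand_sense must be '=' or '>='")
    if formulation == "aggregated":
        return _build_static_aggregated(inst, demand_rhs, demand_sense)
    if formulation == "per_vehicle":
        return _build_static_per_vehicle(inst, demand_rhs, demand_sense, symmetry_break)
    raise ValueError(f"unknown formulation {formulation!r}")


def _build_static_aggregated(
    inst: Instance, demand: Mapping[tuple[str, str], int], demand_sense: str
) -> MILPModel:
    m = MILPModel(tag="static/aggregated")
    road_c, air_c = objective_terms(inst)
    I, J, K = inst.areas, inst.temp_candidates, inst.general_candidates
    gamma, lam = inst.fleet.n_vehicles, inst.fleet.n_helicopters
    eg, eh = inst.fleet.vehicle_capacity, inst.fleet.helicopter_capacity

    for j in J:
        m.add_var(f"U[{j}]", domain=BINARY)
    for k in K:
        m.add_var(f"V[{k}]", domain=BINARY)
    for i in I:
        for j in J:
            for s in SEVERITIES:
                m.add_var(f"x[{i},{j},{s}]", domain=INTEGER, obj=road_c[(i, j, s)])
            m.add_var(f"n[{i},{j}]", domain=INTEGER)
    for j in J:
        for k in K:
            for s in SEVERITIES:
                m.add_var(f"y[{j},{k},{s}]", domain=INTEGER, obj=air_c[(j, k, s)])
            m.add_var(f"m[{j},{k}]", domain=INTEGER)

    for i in I:
        for s in SEVERITIES:
            m.add_constr(
                f"demand[{i},{s}]",
                {f"x[{i},{j},{s}]": 1.0 for j in J},
                demand_sense,
                demand[(i, s)],
            )
    for j in J:
        m.add_constr(
            f"temp_cap[{j}]",
            {f"x[{i},{j},{s}]": 1.0 for i in I for s in SEVERITIES},
            "<=",
            inst.temp_cap(j),
        )
    for k in K:
        for s in SEVERITIES:
            m.add_constr(
                f"gen_cap[{k},{s}]",
                {f"y[{j},{k},{s}]": 1.0 for j in J},
                "<=",
                inst.general_cap(k, s),
            )
    for j in J:
        for s in SEVERITIES:
            coeffs = {f"x[{i},{j},{s}]": 1.0 for i in I}
            coeffs.update({f"y[{j},{k},{s}]": -1.0 for k in K})
            m.add_constr(f"conserve[{j},{s}]", coeffs, "=", 0.0)
    for i in I:
        for j in J:
            load = {f"x[{i},{j},{s}]": 1.0 for s in SEVERITIES}
            load[f"n[{i},{j}]"] = -float(eg)
            m.add_constr(f"veh_load[{i},{j}]", load, "<=", 0.0)
            nonempty = {f"x[{i},{j},{s}]": -1.0 for s in SEVERITIES}
            nonempty[f"n[{i},{j}]"] = 1.0
            m.add_constr(f"veh_nonempty[{i},{j}]", nonempty, "<=", 0.0)
            m.add_constr(
                f"veh_open[{i},{j}]",
                {f"n[{i},{j}]": 1.0, f"U[{j}]": -float(gamma)},
                "<=",
                0.0,
            )
    for j in J:
        for k in K:
            load = {f"y[{j},{k},{s}]": 1.0 for s in SEVERITIES}
            load[f"m[{j},{k}]"] = -float(eh)
            m.add_constr(f"heli_load[{j},{k}]", load, "<=", 0.0)
            nonempty = {f"y[{j},{k},{s}]": -1.0 for s in SEVERITIES}
            nonempty[f"m[{j},{k}]"] = 1.0
            m.add_constr(f"heli_nonempty[{j},{k}]", nonempty, "<=", 0.0)
            m.add_constr(
                f"heli_open[{j},{k}]",
                {f"m[{j},{k}]": 1.0, f"V[{k}]": -float(lam)},
                "<=",
                0.0,
            )
    m.add_constr(
        "fleet_vehicles", {f"n[{i},{j}]": 1.0 for i in I for j in J}, "<=", gamma
    )
    m.add_constr(
        "fleet_helicopters", {f"m[{j},{k}]": 1.0 for j in J for k in K}, "<=", lam
    )
    for j in J:
        coeffs = {f"n[{i},{j}]": 1.0 for i in I}
        coeffs[f"U[{j}]"] = -1.0
        m.add_constr(f"open_served[{j}]", coeffs, ">=", 0.0)
    for k in K:
        coeffs = {f"m[{j},{k}]": 1.0 for j in J}
        coeffs[f"V[{k}]"] = -1.0
        m.add_constr(f"open_served[{k}]", coeffs, ">=", 0.0)
    return m


def _build_static_per_vehicle(
    inst: Instance,
    demand: Mapping[tuple[str, str], int],
    demand_sense: str,
    symmetry_break: bool,
) -> MILPModel:
    m = MILPModel(tag="static/per_vehicle")
    road_c, air_c = objective_terms(inst)
    I, J, K = inst.areas, inst.temp_candidates, inst.general_candidates
    G = range(1, inst.fleet.n_vehicles + 1)
    H = range(1, inst.fleet.n_helicopters + 1)
    eg, eh = inst.fleet.vehicle_capacity, inst.fleet.helicopter_capacity

    for j in J:
        m.add_var(f"U[{j}]", domain=BINARY)
    for k in K:
        m.add_var(f"V[{k}]", domain=BINARY)
    for i in I:
        for j in J:
            for g in G:
                m.add_var(f"X[{i},{j},{g}]", domain=BINARY)
                for s in SEVERITIES:
                    m.add_var(
                        f"x[{i},{j},{g},{s}]",
                        upper=eg,
                        domain=INTEGER,
                        obj=road_c[(i, j, s)],
                    )
    for j in J:
        for k in K:
            for h in H:
                m.add_var(f"Y[{j},{k},{h}]", domain=BINARY)
                for s in SEVERITIES:
                    m.add_var(
                        f"y[{j},{k},{h},{s}]",
                        upper=eh,
                        domain=INTEGER,
                        obj=air_c[(j, k, s)],
                    )

    for i in I:
        for s in SEVERITIES:
            m.add_constr(
                f"demand[{i},{s}]",
                {f"x[{i},{j},{g},{s}]": 1.0 for j in J for g in G},
                demand_sense,
                demand[(i, s)],
            )
    for j in J:
        m.add_constr(
            f"temp_cap[{j}]",
            {f"x[{i},{j},{g},{s}]": 1.0 for i in I for g in G for s in SEVERITIES},
            "<=",
            inst.temp_cap(j),
        )
    for k in K:
        for s in SEVERITIES:
            m.add_constr(
                f"gen_cap[{k},{s}]",
                {f"y[{j},{k},{h},{s}]": 1.0 for j in J for h in H},
                "<=",
                inst.general_cap(k, s),
            )
    for j in J:
        for s in SEVERITIES:
            coeffs = {f"x[{i},{j},{g},{s}]": 1.0 for i in I for g in G}
            coeffs.update({f"y[{j},{k},{h},{s}]": -1.0 for k in K for h in H})
            m.add_constr(f"conserve[{j},{s}]", coeffs, "=", 0.0)
    for g in G:
        m.add_constr(
            f"one_arc_veh[{g}]",
            {f"X[{i},{j},{g}]": 1.0 for i in I for j in J},
            "<=",
            1.0,
        )
        for i in I:
            for j in J:
                load = {f"x[{i},{j},{g},{s}]": 1.0 for s in SEVERITIES}
                load[f"X[{i},{j},{g}]"] = -float(eg)
                m.add_constr(f"veh_load[{i},{j},{g}]", load, "<=", 0.0)
                nonempty = {f"x[{i},{j},{g},{s}]": -1.0 for s in SEVERITIES}
                nonempty[f"X[{i},{j},{g}]"] = 1.0
                m.add_constr(f"veh_nonempty[{i},{j},{g}]", nonempty, "<=", 0.0)
        for j in J:
            coeffs = {f"X[{i},{j},{g}]": 1.0 for i in I}
            coeffs[f"U[{j}]"] = -1.0
            m.add_constr(f"veh_from_open[{j},{g}]", coeffs, "<=", 0.0)
    for h in H:
        m.add_constr(
            f"one_arc_heli[{h}]",
            {f"Y[{j},{k},{h}]": 1.0 for j in J for k in K},
            "<=",
            1.0,
        )
        for j in J:
            for k in K:
                load = {f"y[{j},{k},{h},{s}]": 1.0 for s in SEVERITIES}
                load[f"Y[{j},{k},{h}]"] = -float(eh)
                m.add_constr(f"heli_load[{j},{k},{h}]", load, "<=", 0.0)
                nonempty = {f"y[{j},{k},{h},{s}]": -1.0 for s in SEVERITIES}
                nonempty[f"Y[{j},{k},{h}]"] = 1.0
                m.add_constr(f"heli_nonempty[{j},{k},{h}]", nonempty, "<=", 0.0)
        for k in K:
            coeffs = {f"Y[{j},{k},{h}]": 1.0 for j in J}
            coeffs[f"V[{k}]"] = -1.0
            m.add_constr(f"heli_from_open[{k},{h}]", coeffs, "<=", 0.0)
    for j in J:
        coeffs = {f"X[{i},{j},{g}]": 1.0 for i in I for g in G}
        coeffs[f"U[{j}]"] = -1.0
        m.add_constr(f"open_served[{j}]", coeffs, ">=", 0.0)
    for k in K:
        coeffs = {f"Y[{j},{k},{h}]": 1.0 for j in J for h in H}
        coeffs[f"V[{k}]"] = -1.0
        m.add_constr(f"open_served[{k}]", coeffs, ">=", 0.0)
    m.add_constr(
        "fleet_vehicles",
        {f"X[{i},{j},{g}]": 1.0 for i in I for j in J for g in G},
        "<=",
        inst.fleet.n_vehicles,
    )
    m.add_constr(
        "fleet_helicopters",
        {f"Y[{j},{k},{h}]": 1.0 for j in J for k in K for h in H},
        "<=",
        inst.fleet.n_helicopters,
    )
    if symmetry_break:
        # identical vehicles: vehicle g+1 may only work if vehicle g does
        for g in list(G)[:-1]:
            coeffs = {f"X[{i},{j},{g}]": 1.0 for i in I for j in J}
            coeffs.update({f"X[{i},{j},{g + 1}]": -1.0 for i in I for j in J})
            m.add_constr(f"sym_veh[{g}]", coeffs, ">=", 0.0)
        for h in list(H)[:-1]:
            coeffs = {f"Y[{j},{k},{h}]": 1.0 for j in J for k in K}
            coeffs.update({f"Y[{j},{k},{h + 1}]": -1.0 for j in J for k in K})
            m.add_constr(f"sym_heli[{h}]", coeffs, ">=", 0.0)
    return m


# ---------------------------------------------------------------------------
# Solution extraction


@dataclass
class StaticSolution:
    temp_open: set[str]
    general_open: set[str]
    flows_road: dict[tuple[str, str, str], int]
    flows_air: dict[tuple[str, str, str], int]
    vehicles_used: dict[tuple[str, str], int]
    helicopters_used: dict[tuple[str, str], int]
    F1: float
    F2: float
    objective: float
    solver_status: SolveStatus

    def to_dict(self) -> dict:
        return {
            "temp_open": sorted(self.temp_open),
            "general_open": sorted(self.general_open),
            "flows_road": [
                {"from": i, "to": j, "severity": s, "count": c,
                 "tools": self.vehicles_used.get((i, j), 0)}
                for (i, j, s), c in sorted(self.flows_road.items())
                if c > 0
            ],
            "flows_air": [
                {"from": j, "to": k, "severity": s, "count": c,
                 "tools": self.helicopters_used.get((j, k), 0)}
                for (j, k, s), c in sorted(self.flows_air.items())
                if c > 0
            ],
            "F1": self.F1,
            "F2": self.F2,
            "objective": self.objective,
            "solver_status": self.solver_status.value,
        }


def extract_static_solution(raw: RawSolution, inst: Instance) -> StaticSolution:
    """Aggregate a raw solve into flows per arc and recomputed F1/F2.

    The objective split is recomputed from flows and the coefficient maps and
    cross-checked against the solver's objective (1e-4 tolerance).
    """
    if raw.status is not SolveStatus.OPTIMAL:
        raise ValueError(f"cannot extract from non-optimal solve (status {raw.status.value})")
    road_c, air_c = objective_terms(inst)
    I, J, K = inst.areas, inst.temp_candidates, inst.general_candidates

    def iround(v: float) -> int:
        return int(round(v))

    flows_road: dict[tuple[str, str, str], int] = {}
    flows_air: dict[tuple[str, str, str], int] = {}
    vehicles: dict[tuple[str, str], int] = {}
    helis: dict[tuple[str, str], int] = {}
    per_vehicle = any(name.startswith("X[") for name in raw.values)
    if per_vehicle:
        for name, v in raw.values.items():
            if name.startswith("x[") and v > 1e-6:
                i, j, g, s = name[2:-1].split(",")
                flows_road[(i, j, s)] = flows_road.get((i, j, s), 0) + iround(v)
            elif name.startswith("y[") and v > 1e-6:
                j, k, h, s = name[2:-1].split(",")
                flows_air[(j, k, s)] = flows_air.get((j, k, s), 0) + iround(v)
            elif name.startswith("X[") and v > 0.5:
                i, j, _ = name[2:-1].split(",")
                vehicles[(i, j)] = vehicles.get((i, j), 0) + 1
            elif name.startswith("Y[") and v > 0.5:
                j, k, _ = name[2:-1].split(",")
                helis[(j, k)] = helis.get((j, k), 0) + 1
    else:
        for name, v in raw.values.items():
            if name.startswith("x[") and v > 1e-6:
                i, j, s = name[2:-1].split(",")
                flows_road[(i, j, s)] = iround(v)
            elif name.startswith("y[") and v > 1e-6:
                j, k, s = name[2:-1].split(",")
                flows_air[(j, k, s)] = iround(v)
            elif name.startswith("n[") and v > 1e-6:
                i, j = name[2:-1].split(",")
                vehicles[(i, j)] = iround(v)
            elif name.startswith("m[") and v > 1e-6:
                j, k = name[2:-1].split(",")
                helis[(j, k)] = iround(v)

    F1 = sum(road_c[key] * c for key, c in flows_road.items())
    F2 = sum(air_c[key] * c for key, c in flows_air.items())
    if raw.objective is not None and abs((F1 + F2) - raw.objective) > 1e-4 * max(
        1.0, abs(raw.objective)
    ):
        raise RuntimeError(
            f"recomputed objective {F1 + F2} disagrees with solver objective {raw.objective}"
        )
    temp_open = {j for j in J if raw.values.get(f"U[{j}]", 0.0) > 0.5}
    general_open = {k for k in K if raw.values.get(f"V[{k}]", 0.0) > 0.5}
    return StaticSolution(
        temp_open=temp_open,
        general_open=general_open,
        flows_road=flows_road,
        flows_air=flows_air,
        vehicles_used=vehicles,
        helicopters_used=helis,
        F1=F1,
        F2=F2,
        objective=F1 + F2,
        solver_status=raw.status,
    )


def solve_static(
    inst: Instance,
    demand_rhs: Mapping[tuple[str, str], int] | None = None,
    formulation: str = "aggregated",
    demand_sense: str = "=",
    mip_gap: float = 0.0,
    time_limit: float | None = None,
) -> StaticSolution:
    """Convenience wrapper: build, solve and extract in one call."""
    model = build_static(inst, demand_rhs, formulation, demand_sense)
    raw = solve_milp(model, mip_gap=mip_gap, time_limit=time_limit)
    if raw.status is not SolveStatus.OPTIMAL:
        raise InfeasibleModelError(_diagnose_infeasible(inst, demand_rhs), raw.status)
    return extract_static_solution(raw, inst)


class InfeasibleModelError(RuntimeError):
    def __init__(self, diagnostic: str, status: SolveStatus):
        super().__init__(diagnostic)
        self.status = status


def _diagnose_infeasible(
    inst: Instance, demand_rhs: Mapping[tuple[str, str], int] | None
) -> str:
    demand = dict(demand_rhs) if demand_rhs is not None else inst.nominal_demand()
    total = sum(demand.values())
    checks = []
    temp_total = sum(inst.capacities.temp_capacity[j] for j in inst.temp_candidates)
    if temp_total < total:
        checks.append(f"temporary capacity {temp_total} < demand {total}")
    for s in SEVERITIES:
        ds = sum(v for (_, sev), v in demand.items() if sev == s)
        gen = sum(inst.general_cap(k, s) for k in inst.general_candidates)
        if gen < ds:
            checks.append(f"general capacity for {s} ({gen}) < demand {ds}")
    seats = inst.fleet.n_vehicles * inst.fleet.vehicle_capacity
    if seats < total:
        checks.append(f"vehicle seats {seats} < demand {total}")
    lifts = inst.fleet.n_helicopters * inst.fleet.helicopter_capacity
    if lifts < total:
        checks.append(f"helicopter seats {lifts} < demand {total}")
    if not checks:
        checks.append("no aggregate capacity shortfall found; infeasibility is combinatorial")
    return "model infeasible: " + "; ".join(checks)
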