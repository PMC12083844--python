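"""Problem data model for the three-tier casualty evacuation chain.

An :class:`Instance` describes one planning problem: disaster areas ``I``
holding triaged casualties, candidate temporary hospitals ``J`` reached by
road vehicle, and candidate general hospitals ``K`` reached by helicopter.
Casualties come in two triage classes, *serious* and *moderate*, each with
an urgency weight and an hourly deterioration rate; after first treatment at
a temporary hospital the deterioration rate drops to a fraction of its
pre-treatment value (``post_treatment_factor``, default 0.2).

Instances serialize to a single JSON document or to a CSV bundle (one file
per table).  The 2013 Lushan earthquake case used throughout the test suite
ships with the package; see :func:`lushan_instance`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

SERIOUS = "serious"
MODERATE = "moderate"
SEVERITIES = (SERIOUS, MODERATE)


@dataclass(frozen=True)
class SeverityClass:
    """One triage class: label, objective urgency weight and hourly
    deterioration rate before treatment."""

    label: str
    urgency_weight: float
    base_deterioration: float

    def __post_init__(self) -> None:
        if self.label not in SEVERITIES:
            raise ValueError(f"unknown severity label {self.label!r}")
        if self.urgency_weight <= 0:
            raise ValueError("urgency_weight must be positive")
        if not 0 < self.base_deterioration <= 1:
            raise ValueError("base_deterioration must lie in (0, 1]")


@dataclass
class CasualtyTable:
    """Nominal casualty counts per (area, severity)."""

    counts: dict[tuple[str, str], int]

    def get(self, area: str, severity: str) -> int:
        return self.counts[(area, severity)]

    def total(self, severity: str | None = None) -> int:
        if severity is None:
            return sum(self.counts.values())
        return sum(v for (_, s), v in self.counts.items() if s == severity)

    def area_total(self, area: str) -> int:
        return sum(v for (a, _), v in self.counts.items() if a == area)


@dataclass
class TravelTimes:
    """Road times area->temporary and air times temporary->general, hours."""

    road_hours: dict[tuple[str, str], float]
    air_hours: dict[tuple[str, str], float]


@dataclass
class FleetSpec:
    """Homogeneous rescue fleets: road vehicles and helicopters."""

    n_vehicles: int
    n_helicopters: int
    vehicle_capacity: int
    helicopter_capacity: int


@dataclass
class CapacitySpec:
    """Hospital capacities.

    Temporary hospitals share a nominally uniform head-count capacity but the
    spec is stored per hospital so capacity sweeps can perturb them
    individually.  General hospitals have per-severity capacities.
    """

    temp_capacity: dict[str, int]
    general_capacity: dict[tuple[str, str], int]

    @classmethod
    def uniform(
        cls,
        temp_ids: Iterable[str],
        temp_cap: int,
        general_capacity: dict[tuple[str, str], int],
    ) -> "CapacitySpec":
        return cls({j: temp_cap for j in temp_ids}, dict(general_capacity))


@dataclass
class ValidationReport:
    errors: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def error(self, code: str, message: str) -> None:
        self.errors.append((code, message))

    def warn(self, code: str, message: str) -> None:
        self.warnings.append((code, message))


@dataclass
class Instance:
    areas: list[str]
    temp_candidates: list[str]
    general_candidates: list[str]
    casualties: CasualtyTable
    times: TravelTimes
    fleet: FleetSpec
    capacities: CapacitySpec
    severities: dict[str, SeverityClass]
    post_treatment_factor: float = 0.2
    name: str = "instance"

    def severity(self, label: str) -> SeverityClass:
        return self.severities[label]

    def temp_cap(self, j: str) -> int:
        return self.capacities.temp_capacity[j]

    def general_cap(self, k: str, s: str) -> int:
        return self.capacities.general_capacity[(k, s)]

    def nominal_demand(self) -> dict[tuple[str, str], int]:
        """Demand right-hand side at nominal casualty counts."""
        return dict(self.casualties.counts)


def validate(inst: Instance) -> ValidationReport:
    """Structural validation; model builders reject instances with errors.

    A warning (not an error) is raised when total temporary capacity falls
    short of the nominal casualty total: the instance is then likely
    infeasible at nominal demand, but a caller may still want the model, e.g.
    to diagnose which capacity binds.
    """
    rep = ValidationReport()
    for name, ids in (
        ("areas", inst.areas),
        ("temp_candidates", inst.temp_candidates),
        ("general_candidates", inst.general_candidates),
    ):
        if not ids:
            rep.error("empty-set", f"{name} is empty")
        if len(set(ids)) != len(ids):
            rep.error("duplicate-id", f"{name} contains duplicates")
    all_ids = list(inst.areas) + list(inst.temp_candidates) + list(inst.general_candidates)
    if len(set(all_ids)) != len(all_ids):
        rep.error("overlapping-sets", "area/hospital id sets overlap")

    for a in inst.areas:
        for s in SEVERITIES:
            if (a, s) not in inst.casualties.counts:
                rep.error("missing-count", f"no casualty count for ({a}, {s})")
            else:
                q = inst.casualties.counts[(a, s)]
                if not isinstance(q, int) or q < 0:
                    rep.error("bad-count", f"count for ({a}, {s}) must be a non-negative integer, got {q!r}")
    for a in inst.areas:
        for j in inst.temp_candidates:
            t = inst.times.road_hours.get((a, j))
            if t is None:
                rep.error("missing-road-time", f"no road time for ({a}, {j})")
            elif t <= 0:
                rep.error("bad-road-time", f"road time ({a}, {j}) must be positive, got {t}")
    for j in inst.temp_candidates:
        for k in inst.general_candidates:
            t = inst.times.air_hours.get((j, k))
            if t is None:
                rep.error("missing-air-time", f"no air time for ({j}, {k})")
            elif t <= 0:
                rep.error("bad-air-time", f"air time ({j}, {k}) must be positive, got {t}")

    fl = inst.fleet
    for fname, v in (
        ("n_vehicles", fl.n_vehicles),
        ("n_helicopters", fl.n_helicopters),
        ("vehicle_capacity", fl.vehicle_capacity),
        ("helicopter_capacity", fl.helicopter_capacity),
    ):
        if v < 1:
            rep.error("bad-fleet", f"fleet.{fname} must be >= 1, got {v}")

    for j in inst.temp_candidates:
        if inst.capacities.temp_capacity.get(j, -1) < 0:
            rep.error("bad-temp-capacity", f"temporary capacity for {j} missing or negative")
    for k in inst.general_candidates:
        for s in SEVERITIES:
            if inst.capacities.general_capacity.get((k, s), -1) < 0:
                rep.error("bad-general-capacity", f"general capacity for ({k}, {s}) missing or negative")

    labels = set(inst.severities)
    if labels != set(SEVERITIES):
        rep.error("bad-severities", f"severity classes must be exactly {SEVERITIES}, got {sorted(labels)}")
    else:
        se, mo = inst.severities[SERIOUS], inst.severities[MODERATE]
        if se.urgency_weight < mo.urgency_weight:
            rep.error("weight-order", "serious urgency weight below moderate")
        if se.base_deterioration < mo.base_deterioration:
            rep.error("rate-order", "serious deterioration rate below moderate")

    if not 0 < inst.post_treatment_factor <= 1:
        rep.error("bad-factor", f"post_treatment_factor must lie in (0, 1], got {inst.post_treatment_factor}")

    if rep.ok:
        total = inst.casualties.total()
        temp_total = sum(inst.capacities.temp_capacity[j] for j in inst.temp_candidates)
        if temp_total < total:
            rep.warn(
                "tight-temp-capacity",
                f"total temporary capacity {temp_total} < total nominal casualties {total}; "
                "the nominal model is likely infeasible",
            )
        for s in SEVERITIES:
            gen_total = sum(inst.capacities.general_capacity[(k, s)] for k in inst.general_candidates)
            if gen_total < inst.casualties.total(s):
                rep.warn(
                    "tight-general-capacity",
                    f"total general capacity for {s} ({gen_total}) below nominal demand "
                    f"{inst.casualties.total(s)}",
                )
        seat_total = fl.n_vehicles * fl.vehicle_capacity
        if seat_total < total:
            rep.warn(
                "tight-fleet",
                f"vehicle seat capacity {seat_total} < total nominal casualties {total}",
            )
    return rep


# ---------------------------------------------------------------------------
# Serialization

_SCHEMA_VERSION = 1


def instance_to_dict(inst: Instance) -> dict:
    return {
        "schema_version": _SCHEMA_VERSION,
        "name": inst.name,
        "areas": list(inst.areas),
        "temp_hospitals": list(inst.temp_candidates),
        "general_hospitals": list(inst.general_candidates),
        "casualties": [
            {"area": a, "severity": s, "count": c}
            for (a, s), c in sorted(inst.casualties.counts.items())
        ],
        "road_times": [
            {"from": a, "to": j, "hours": t}
            for (a, j), t in sorted(inst.times.road_hours.items())
        ],
        "air_times": [
            {"from": j, "to": k, "hours": t}
            for (j, k), t in sorted(inst.times.air_hours.items())
        ],
        "fleet": {
            "n_vehicles": inst.fleet.n_vehicles,
            "n_helicopters": inst.fleet.n_helicopters,
            "vehicle_capacity": inst.fleet.vehicle_capacity,
            "helicopter_capacity": inst.fleet.helicopter_capacity,
        },
        "capacities": {
            "temporary": dict(sorted(inst.capacities.temp_capacity.items())),
            "general": [
                {"hospital": k, "severity": s, "capacity": c}
                for (k, s), c in sorted(inst.capacities.general_capacity.items())
            ],
        },
        "severity_params": {
            lab: {
                "urgency_weight": sc.urgency_weight,
                "base_deterioration": sc.base_deterioration,
            }
            for lab, sc in inst.severities.items()
        },
        "post_treatment_factor": inst.post_treatment_factor,
    }


def instance_from_dict(d: dict) -> Instance:
    def need(key: str):
        if key not in d:
            raise ValueError(f"instance document missing key {key!r}")
        return d[key]

    casualties = CasualtyTable(
        {(r["area"], r["severity"]): int(r["count"]) for r in need("casualties")}
    )
    times = TravelTimes(
        {(r["from"], r["to"]): float(r["hours"]) for r in need("road_times")},
        {(r["from"], r["to"]): float(r["hours"]) for r in need("air_times")},
    )
    fl = need("fleet")
    caps = need("capacities")
    sev = need("severity_params")
    inst = Instance(
        areas=list(need("areas")),
        temp_candidates=list(need("temp_hospitals")),
        general_candidates=list(need("general_hospitals")),
        casualties=casualties,
        times=times,
        fleet=FleetSpec(
            int(fl["n_vehicles"]),
            int(fl["n_helicopters"]),
            int(fl["vehicle_capacity"]),
            int(fl["helicopter_capacity"]),
        ),
        capacities=CapacitySpec(
            {j: int(c) for j, c in caps["temporary"].items()},
            {(r["hospital"], r["severity"]): int(r["capacity"]) for r in caps["general"]},
        ),
        severities={
            lab: SeverityClass(lab, float(p["urgency_weight"]), float(p["base_deterioration"]))
            for lab, p in sev.items()
        },
        post_treatment_factor=float(d.get("post_treatment_factor", 0.2)),
        name=str(d.get("name", "instance")),
    )
    rep = validate(inst)
    if not rep.ok:
        raise ValueError("invalid instance: " + "; ".join(m for _, m in rep.errors))
    return inst


def save_instance(inst: Instance, path: str | Path) -> None:
    Path(path).write_text(json.dumps(instance_to_dict(inst), indent=1))


def load_instance(path: str | Path, format: str = "auto") -> Instance:
    """Load an instance from a JSON document or a CSV bundle directory."""
    path = Path(path)
    if format == "auto":
        format = "csv-bundle" if path.is_dir() else "json"
    if format == "json":
        return instance_from_dict(json.loads(path.read_text()))
    if format == "csv-bundle":
        return _load_csv_bundle(path)
    raise ValueError(f"unknown instance format {format!r}")


_BUNDLE_FILES = (
    "casualties.csv",
    "road_times.csv",
    "air_times.csv",
    "fleet.csv",
    "capacities.csv",
    "severity_params.csv",
)


def save_csv_bundle(inst: Instance, directory: str | Path) -> None:
    import pandas as pd

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    doc = instance_to_dict(inst)
    pd.DataFrame(doc["casualties"]).to_csv(d / "casualties.csv", index=False)
    pd.DataFrame(doc["road_times"]).to_csv(d / "road_times.csv", index=False)
    pd.DataFrame(doc["air_times"]).to_csv(d / "air_times.csv", index=False)
    pd.DataFrame([doc["fleet"]]).to_csv(d / "fleet.csv", index=False)
    caps = [
        {"hospital": j, "severity": "", "capacity": c, "tier": "temporary"}
        for j, c in doc["capacities"]["temporary"].items()
    ] + [
        {**r, "tier": "general"} for r in doc["capacities"]["general"]
    ]
    pd.DataFrame(caps).to_csv(d / "capacities.csv", index=False)
    sev = [
        {"label": lab, **p} for lab, p in doc["severity_params"].items()
    ]
    sev.append(
        {
            "label": "post_treatment_factor",
            "urgency_weight": "",
            "base_deterioration": doc["post_treatment_factor"],
        }
    )
    pd.DataFrame(sev).to_csv(d / "severity_params.csv", index=False)


def _load_csv_bundle(directory: Path) -> Instance:
    import pandas as pd

    for f in _BUNDLE_FILES:
        if not (directory / f).exists():
            raise ValueError(f"CSV bundle missing {f}")
    cas = pd.read_csv(directory / "casualties.csv")
    road = pd.read_csv(directory / "road_times.csv")
    air = pd.read_csv(directory / "air_times.csv")
    fleet = pd.read_csv(directory / "fleet.csv").iloc[0]
    caps = pd.read_csv(directory / "capacities.csv")
    sev = pd.read_csv(directory / "severity_params.csv")

    factor = 0.2
    severities = {}
    for _, r in sev.iterrows():
        if r["label"] == "post_treatment_factor":
            factor = float(r["base_deterioration"])
        else:
            severities[r["label"]] = {
                "urgency_weight": float(r["urgency_weight"]),
                "base_deterioration": float(r["base_deterioration"]),
            }
    temp_caps = caps[caps["tier"] == "temporary"]
    gen_caps = caps[caps["tier"] == "general"]
    doc = {
        "areas": sorted(cas["area"].unique().tolist()),
        "temp_hospitals": sorted(temp_caps["hospital"].unique().tolist()),
        "general_hospitals": sorted(gen_caps["hospital"].unique().tolist()),
        "casualties": cas.to_dict("records"),
        "road_times": road.to_dict("records"),
        "air_times": air.to_dict("records"),
        "fleet": fleet.to_dict(),
        "capacities": {
            "temporary": {r["hospital"]: int(r["capacity"]) for _, r in temp_caps.iterrows()},
            "general": gen_caps.to_dict("records"),
        },
        "severity_params": severities,
        "post_treatment_factor": factor,
        "name": directory.name,
    }
    return instance_from_dict(doc)


def lushan_instance() -> Instance:
    """The embedded 2013 Lushan earthquake case.

    Nine disaster areas, five candidate temporary hospitals, three candidate
    general hospitals; 255 serious and 730 moderate casualties.  Severity
    parameters: urgency weights 2 (serious) / 1 (moderate), deterioration
    rates 0.8 / 0.2 per hour, post-treatment slowdown factor 0.2; temporary
    capacity 500 per hospital.

    The fleet has 280 road vehicles (6 seats) and 150 helicopters (12 seats).
    The case's published tabulation lists the two quantities the other way
    around, but under that reading total vehicle seat capacity (900) cannot
    move the 985 casualties and the case has no feasible plan, contradicting
    the solutions reported for it; the assignment used here is the only one
    consistent with those solutions.
    """
    with resources.files("casevac.data").joinpath("lushan.json").open() as fh:
        return instance_from_dict(json.load(fh))
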