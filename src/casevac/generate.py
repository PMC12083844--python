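"""Seeded generator of synthetic evacuation instances.

Instances mimic the structure of the embedded earthquake case: casualty
counts drawn uniformly per severity class (default ranges match the case's
spread: serious 5-70, moderate 23-153 per area), i.i.d. travel times rounded
to three decimals, and capacity/fleet policies that leave a configurable
slack factor above nominal demand so the nominal model is always feasible.
Geography is not modelled; i.i.d. times are sufficient to exercise the
optimization models.

All randomness flows through ``numpy.random.default_rng(seed)``, so a given
parameter set reproduces the identical instance on any platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .instance import (
    MODERATE,
    SERIOUS,
    SEVERITIES,
    CapacitySpec,
    CasualtyTable,
    FleetSpec,
    Instance,
    SeverityClass,
    TravelTimes,
)
from .robust import UncertaintySpec, _round


@dataclass
class GeneratorParams:
    n_areas: int = 9
    n_temp: int = 5
    n_general: int = 3
    seed: int = 0
    serious_range: tuple[int, int] = (5, 70)
    moderate_range: tuple[int, int] = (23, 153)
    road_time_range: tuple[float, float] = (0.4, 2.5)
    air_time_range: tuple[float, float] = (0.55, 0.75)
    vehicle_capacity: int = 6
    helicopter_capacity: int = 12
    capacity_slack: float = 1.2
    fleet_slack: float = 1.3
    urgency_weights: tuple[float, float] = (2.0, 1.0)
    deterioration_rates: tuple[float, float] = (0.8, 0.2)
    post_treatment_factor: float = 0.2
    fleet_override: tuple[int, int] | None = None  # (n_vehicles, n_helicopters)

    def __post_init__(self) -> None:
        for name in ("n_areas", "n_temp", "n_general"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("serious_range", "moderate_range", "road_time_range", "air_time_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive non-empty interval")


def generate_instance(params: GeneratorParams) -> Instance:
    """Draw one instance; deterministic for a fixed parameter set."""
    rng = np.random.default_rng(params.seed)
    areas = [f"I{i}" for i in range(1, params.n_areas + 1)]
    temps = [f"J{j}" for j in range(1, params.n_temp + 1)]
    gens = [f"K{k}" for k in range(1, params.n_general + 1)]

    counts: dict[tuple[str, str], int] = {}
    for a in areas:
        counts[(a, SERIOUS)] = int(
            rng.integers(params.serious_range[0], params.serious_range[1] + 1)
        )
        counts[(a, MODERATE)] = int(
            rng.integers(params.moderate_range[0], params.moderate_range[1] + 1)
        )
    total = sum(counts.values())
    totals_by_sev = {
        s: sum(v for (_, sev), v in counts.items() if sev == s) for s in SEVERITIES
    }

    road = {
        (a, j): round(float(rng.uniform(*params.road_time_range)), 3)
        for a in areas
        for j in temps
    }
    air = {
        (j, k): round(float(rng.uniform(*params.air_time_range)), 3)
        for j in temps
        for k in gens
    }

    temp_cap = math.ceil(params.capacity_slack * total / params.n_temp)
    general_capacity = {
        (k, s): math.ceil(params.capacity_slack * totals_by_sev[s] / params.n_general)
        for k in gens
        for s in SEVERITIES
    }
    if params.fleet_override is not None:
        n_veh, n_heli = params.fleet_override
    else:
        n_veh = math.ceil(params.fleet_slack * total / params.vehicle_capacity)
        n_heli = math.ceil(params.fleet_slack * total / params.helicopter_capacity)

    ws, wm = params.urgency_weights
    ps, pm = params.deterioration_rates
    return Instance(
        areas=areas,
        temp_candidates=temps,
        general_candidates=gens,
        casualties=CasualtyTable(counts),
        times=TravelTimes(road, air),
        fleet=FleetSpec(n_veh, n_heli, params.vehicle_capacity, params.helicopter_capacity),
        capacities=CapacitySpec.uniform(temps, temp_cap, general_capacity),
        severities={
            SERIOUS: SeverityClass(SERIOUS, ws, ps),
            MODERATE: SeverityClass(MODERATE, wm, pm),
        },
        post_treatment_factor=params.post_treatment_factor,
        name=f"synthetic-{params.n_areas}x{params.n_temp}x{params.n_general}-seed{params.seed}",
    )


def perturb_realization(
    inst: Instance, unc: UncertaintySpec, seed: int
) -> CasualtyTable:
    """Sample one demand realization from the interval uncertainty set.

    Each realized count is uniform on the integer interval
    ``[q - q_hat, q + q_hat]`` with ``q_hat`` the rounded maximum deviation;
    cells are independent.  The uncertainty-set geometry fixes only the
    support, not a distribution; uniform sampling is this package's
    documented choice for plan stress-testing.
    """
    rng = np.random.default_rng(seed)
    realized: dict[tuple[str, str], int] = {}
    for (a, s), q in sorted(inst.casualties.counts.items()):
        q_hat = _round(unc.variability * q, unc.rounding)
        lo = max(0, q - q_hat)
        realized[(a, s)] = int(rng.integers(lo, q + q_hat + 1))
    return CasualtyTable(realized)
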