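"""Deterioration accrued in transit and the weighted objective coefficients.

A casualty of severity class ``s`` deteriorates at ``p_s`` score points per
hour before treatment.  A leg with one-way travel time ``t`` hours accrues
``2 * t * p_s`` (the factor 2 covers the vehicle round trip).  After first
treatment at a temporary hospital the hourly rate drops to
``factor * p_s`` (factor 0.2 by default), so the air leg accrues
``2 * t * factor * p_s``.

In the multi-period model a casualty still waiting in period ``t`` has
already deteriorated for ``(t - 1) * dt`` hours, so the per-casualty accrual
becomes ``p_s * ((t - 1) * dt + 2 * travel)`` pre-treatment and
``factor * p_s * ((t - 1) * dt + 2 * travel)`` post-treatment; at ``t = 1``
these reduce to the static forms.

Objective coefficients multiply the accrual by the class urgency weight
``w_s``.
"""

from __future__ import annotations

from .instance import SEVERITIES, Instance, SeverityClass


def pre_rate(travel_time_h: float, sev: SeverityClass) -> float:
    """Score accrued per casualty on the road leg (pre-treatment)."""
    if travel_time_h < 0:
        raise ValueError("travel time must be non-negative")
    return 2.0 * travel_time_h * sev.base_deterioration


def post_rate(travel_time_h: float, sev: SeverityClass, factor: float = 0.2) -> float:
    """Score accrued per casualty on the air leg (post-treatment)."""
    if travel_time_h < 0:
        raise ValueError("travel time must be non-negative")
    if not 0 < factor <= 1:
        raise ValueError("post-treatment factor must lie in (0, 1]")
    return 2.0 * travel_time_h * factor * sev.base_deterioration


def dynamic_pre_rate(
    travel_time_h: float, sev: SeverityClass, period: int, dt: float
) -> float:
    """Pre-treatment accrual for a casualty moved in period ``period``."""
    if travel_time_h < 0:
        raise ValueError("travel time must be non-negative")
    if period < 1:
        raise ValueError("period index must be >= 1")
    if dt < 0:
        raise ValueError("period length must be non-negative")
    return sev.base_deterioration * ((period - 1) * dt + 2.0 * travel_time_h)


def dynamic_post_rate(
    travel_time_h: float,
    sev: SeverityClass,
    period: int,
    dt: float,
    factor: float = 0.2,
) -> float:
    """Post-treatment accrual for a casualty moved onward in period ``period``."""
    if travel_time_h < 0:
        raise ValueError("travel time must be non-negative")
    if period < 1:
        raise ValueError("period index must be >= 1")
    if factor < 0:
        raise ValueError("post-treatment factor must be non-negative")
    return factor * sev.base_deterioration * ((period - 1) * dt + 2.0 * travel_time_h)


def objective_terms(
    inst: Instance,
) -> tuple[dict[tuple[str, str, str], float], dict[tuple[str, str, str], float]]:
    """Per-casualty objective coefficients for both legs.

    Returns ``(road, air)`` maps: ``road[(i, j, s)]`` is the weighted score a
    class-``s`` casualty accrues travelling area ``i`` -> temporary ``j``;
    ``air[(j, k, s)]`` likewise for temporary ``j`` -> general ``k``.
    """
    road: dict[tuple[str, str, str], float] = {}
    air: dict[tuple[str, str, str], float] = {}
    for s in SEVERITIES:
        sev = inst.severity(s)
        w = sev.urgency_weight
        for i in inst.areas:
            for j in inst.temp_candidates:
                road[(i, j, s)] = pre_rate(inst.times.road_hours[(i, j)], sev) * w
        for j in inst.temp_candidates:
            for k in inst.general_candidates:
                air[(j, k, s)] = (
                    post_rate(inst.times.air_hours[(j, k)], sev, inst.post_treatment_factor) * w
                )
    return road, air
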