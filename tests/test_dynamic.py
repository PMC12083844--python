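"""Multi-period dynamic model."""

import pytest

import casevac as cv


class TestFleetAvailability:
    def test_recursion_by_hand(self):
        assert cv.fleet_availability(150, [40, 30]) == [150, 110, 120]

    def test_idle_fleet_constant(self):
        assert cv.fleet_availability(150, [0, 0, 0]) == [150, 150, 150, 150]

    def test_overuse_raises(self):
        with pytest.raises(ValueError, match="period 2"):
            cv.fleet_availability(150, [150, 150])

    def test_tools_return_after_one_period(self):
        # all tools out in period 1 are back for period 3
        assert cv.fleet_availability(10, [10, 0, 10]) == [10, 0, 10, 0]


class TestPeriodSpec:
    def test_bad_values_rejected(self):
        with pytest.raises(ValueError):
            cv.PeriodSpec(0, 1.0)
        with pytest.raises(ValueError):
            cv.PeriodSpec(2, 0.0)


class TestTwoStageModel:
    def test_single_period_equals_static(self, small_instance):
        static = cv.solve_static(small_instance)
        dyn = cv.solve_two_stage(small_instance, cv.PeriodSpec(1, 1.0))
        assert dyn.objective == pytest.approx(static.objective, abs=1e-6)

    def test_solution_invariants(self, small_instance):
        inst = small_instance
        periods = cv.PeriodSpec(2, 1.0)
        sol = cv.solve_two_stage(inst, periods)
        # per-period conservation at each temporary hospital
        for j in inst.temp_candidates:
            for s in cv.SEVERITIES:
                for t in periods.periods:
                    inflow = sum(
                        sol.flows_road.get((i, j, s, t), 0) for i in inst.areas
                    )
                    outflow = sum(
                        sol.flows_air.get((j, k, s, t), 0)
                        for k in inst.general_candidates
                    )
                    assert inflow == outflow
        # cumulative capacities
        for j in inst.temp_candidates:
            total = sum(
                sol.flows_road.get((i, j, s, t), 0)
                for i in inst.areas
                for s in cv.SEVERITIES
                for t in periods.periods
            )
            assert total <= inst.temp_cap(j)
        for k in inst.general_candidates:
            for s in cv.SEVERITIES:
                total = sum(
                    sol.flows_air.get((j, k, s, t), 0)
                    for j in inst.temp_candidates
                    for t in periods.periods
                )
                assert total <= inst.general_cap(k, s)
        # every casualty moved exactly once
        moved = sum(sol.flows_road.values())
        assert moved == inst.casualties.total()
        # the availability recursion admits the realized usage
        assert sol.vehicle_avail[0] == inst.fleet.n_vehicles
        assert all(a >= 0 for a in sol.vehicle_avail)

    def test_nominal_prefers_early_movement(self, small_instance):
        """Deterioration grows with waiting, so with ample fleet everything
        moves in period 1 and the optimum matches the static model."""
        static = cv.solve_static(small_instance)
        dyn = cv.solve_two_stage(small_instance, cv.PeriodSpec(2, 1.0))
        assert dyn.objective == pytest.approx(static.objective, abs=1e-6)
        period2 = sum(c for (_, _, _, t), c in sol_items(dyn) if t == 2)
        assert period2 == 0

    def test_robust_needs_two_periods(self, small_instance):
        with pytest.raises(cv.InfeasibleModelError, match="T >= 2"):
            cv.build_two_stage(
                small_instance, cv.PeriodSpec(1, 1.0), cv.UncertaintySpec(0.20, 1.0)
            )

    def test_robust_spreads_and_costs_more(self, lushan):
        # tiny casualty counts make the printed per-period cap q - q_hat*Gamma'
        # non-positive, so this property is exercised on the embedded case
        nominal = cv.solve_two_stage(lushan, cv.PeriodSpec(2, 1.0))
        objs = []
        for gamma in (0.4, 1.0):
            sol = cv.solve_two_stage(
                lushan, cv.PeriodSpec(2, 1.0), cv.UncertaintySpec(0.20, gamma)
            )
            objs.append(sol.objective)
            # the per-period cap binds below nominal demand, so period 2 is used
            period2 = sum(c for (_, _, _, t), c in sol_items(sol) if t == 2)
            assert period2 > 0
        assert nominal.objective <= objs[0] <= objs[1]


def sol_items(sol):
    return sol.flows_road.items()
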