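"""Static MILP: builders, solver backend, extraction and invariants."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import casevac as cv
from conftest import small_params


class TestVehiclesRequired:
    @pytest.mark.parametrize("flow, cap, expected", [(202, 6, 34), (0, 6, 0), (6, 6, 1)])
    def test_examples(self, flow, cap, expected):
        assert cv.vehicles_required(flow, cap) == expected

    @given(flow=st.integers(0, 10_000), cap=st.integers(1, 50))
    @settings(max_examples=100, deadline=None)
    def test_matches_ceiling_division(self, flow, cap):
        assert cv.vehicles_required(flow, cap) == math.ceil(flow / cap)

    def test_zero_capacity_rejected(self):
        with pytest.raises(ValueError):
            cv.vehicles_required(5, 0)


class TestModelShape:
    def test_aggregated_variable_count(self, lushan):
        model = cv.build_static(lushan)
        # 90 road flows + 30 air flows + 45 + 15 arc counts + 8 binaries
        assert model.n_vars == 90 + 30 + 45 + 15 + 8
        binaries = [v for v in model.variables if v.domain == "binary"]
        assert len(binaries) == 8

    def test_per_vehicle_variable_count(self, small_instance):
        model = cv.build_static(small_instance, formulation="per_vehicle")
        I, J, K = 3, 2, 2
        G = H = 12
        expected = (
            J + K  # openings
            + I * J * G * 3  # X plus two severity flows
            + J * K * H * 3
        )
        assert model.n_vars == expected

    def test_unknown_formulation_rejected(self, small_instance):
        with pytest.raises(ValueError, match="formulation"):
            cv.build_static(small_instance, formulation="magic")

    def test_lp_export_sections(self, small_instance, tmp_path):
        text = cv.build_static(small_instance).to_lp()
        for section in ("Minimize", "Subject To", "Generals", "Binaries", "End"):
            assert section in text


class TestSolveAndExtract:
    def test_zero_demand_gives_empty_plan(self, small_instance):
        zero = {(i, s): 0 for i in small_instance.areas for s in cv.SEVERITIES}
        sol = cv.solve_static(small_instance, demand_rhs=zero)
        assert sol.objective == 0
        assert sol.flows_road == {} and sol.flows_air == {}
        assert sol.temp_open == set() and sol.general_open == set()

    def test_infeasible_toy_raises_with_diagnostic(self, small_instance):
        import dataclasses

        caps = dataclasses.replace(small_instance.capacities)
        caps.temp_capacity = {j: 1 for j in small_instance.temp_candidates}
        tiny = dataclasses.replace(small_instance, capacities=caps)
        with pytest.raises(cv.InfeasibleModelError, match="temporary capacity"):
            cv.solve_static(tiny)

    def test_extraction_requires_optimal(self, small_instance):
        raw = cv.RawSolution(status=cv.SolveStatus.INFEASIBLE, objective=None, values={})
        with pytest.raises(ValueError, match="non-optimal"):
            cv.extract_static_solution(raw, small_instance)

    def test_solution_invariants(self, small_instance):
        inst = small_instance
        sol = cv.solve_static(inst)
        # objective identity
        assert sol.objective == pytest.approx(sol.F1 + sol.F2)
        # demand satisfied exactly
        for i in inst.areas:
            for s in cv.SEVERITIES:
                shipped = sum(sol.flows_road.get((i, j, s), 0) for j in inst.temp_candidates)
                assert shipped == inst.casualties.get(i, s)
        # conservation at each temporary hospital
        for j in inst.temp_candidates:
            for s in cv.SEVERITIES:
                inflow = sum(sol.flows_road.get((i, j, s), 0) for i in inst.areas)
                outflow = sum(
                    sol.flows_air.get((j, k, s), 0) for k in inst.general_candidates
                )
                assert inflow == outflow
        # capacities respected
        for j in inst.temp_candidates:
            intake = sum(
                sol.flows_road.get((i, j, s), 0)
                for i in inst.areas
                for s in cv.SEVERITIES
            )
            assert intake <= inst.temp_cap(j)
        for k in inst.general_candidates:
            for s in cv.SEVERITIES:
                intake = sum(sol.flows_air.get((j, k, s), 0) for j in inst.temp_candidates)
                assert intake <= inst.general_cap(k, s)
        # nothing routed through unopened hospitals
        for (i, j, s), c in sol.flows_road.items():
            if c > 0:
                assert j in sol.temp_open
        for (j, k, s), c in sol.flows_air.items():
            if c > 0:
                assert k in sol.general_open
        # optimal tool counts are exactly the ceiling of arc loads
        for (i, j), n in sol.vehicles_used.items():
            load = sum(sol.flows_road.get((i, j, s), 0) for s in cv.SEVERITIES)
            assert n == cv.vehicles_required(load, inst.fleet.vehicle_capacity)

    @pytest.mark.parametrize("seed", range(5))
    def test_aggregated_equals_per_vehicle(self, seed):
        """Identical vehicles make the arc-count reformulation objective-exact."""
        inst = cv.generate_instance(small_params(seed))
        agg = cv.solve_static(inst, formulation="aggregated")
        pv = cv.solve_static(inst, formulation="per_vehicle")
        assert agg.objective == pytest.approx(pv.objective, abs=1e-6)

    def test_per_vehicle_symmetry_breaking_preserves_optimum(self, small_instance):
        m_sym = cv.build_static(small_instance, formulation="per_vehicle", symmetry_break=True)
        m_raw = cv.build_static(small_instance, formulation="per_vehicle", symmetry_break=False)
        obj_sym = cv.solve_milp(m_sym).objective
        obj_raw = cv.solve_milp(m_raw).objective
        assert obj_sym == pytest.approx(obj_raw, abs=1e-6)
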