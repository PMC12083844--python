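"""Budget-of-uncertainty robust counterpart."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import casevac as cv
from conftest import small_params


class TestInflatedDemand:
    @pytest.mark.parametrize(
        "q, delta, gamma, rounding, expected",
        [
            (59, 0.20, 1.0, "half_up", 71),  # 59 + round(11.8)
            (143, 0.05, 0.2, "half_up", 144),  # 143 + round(1.43)
            (143, 0.05, 0.2, "ceil", 145),
            (143, 0.05, 0.2, "floor", 144),
            (59, 0.15, 0.2, "ceil", 61),  # 59 + ceil(1.77)
        ],
    )
    def test_examples(self, q, delta, gamma, rounding, expected):
        assert cv.inflated_demand(q, delta, gamma, rounding) == expected

    @given(q=st.integers(0, 500), delta=st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_zero_budget_is_nominal(self, q, delta):
        assert cv.inflated_demand(q, delta, 0.0) == q

    @given(
        q=st.integers(0, 500),
        delta=st.floats(0, 1),
        g1=st.floats(0, 1),
        g2=st.floats(0, 1),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_budget(self, q, delta, g1, g2):
        lo, hi = sorted((g1, g2))
        assert cv.inflated_demand(q, delta, lo) <= cv.inflated_demand(q, delta, hi)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cv.inflated_demand(10, 1.5, 0.5)
        with pytest.raises(ValueError):
            cv.inflated_demand(10, 0.5, -0.1)

    def test_product_invariance_of_tables(self, lushan):
        """Inflation depends on delta and Gamma only through their product."""
        a = cv.inflated_demand_table(lushan, cv.UncertaintySpec(0.05, 0.8))
        b = cv.inflated_demand_table(lushan, cv.UncertaintySpec(0.20, 0.2))
        assert a == b


class TestUncertaintySpec:
    def test_scalar_budget_broadcasts(self, lushan):
        unc = cv.UncertaintySpec(0.1, 0.5)
        assert all(unc.gamma(i) == 0.5 for i in lushan.areas)

    def test_per_area_budget(self, lushan):
        budget = {i: 0.0 for i in lushan.areas}
        budget["I1"] = 1.0
        unc = cv.UncertaintySpec(0.2, budget)
        table = cv.inflated_demand_table(lushan, unc)
        assert table[("I1", cv.SERIOUS)] == 59 + 12
        assert table[("I2", cv.SERIOUS)] == 21

    def test_bad_rounding_rejected(self):
        with pytest.raises(ValueError, match="rounding"):
            cv.UncertaintySpec(0.1, 0.5, "banker")


class TestRobustModel:
    def test_zero_budget_reproduces_deterministic(self, small_instance):
        det = cv.solve_static(small_instance)
        rob = cv.solve_robust(small_instance, cv.UncertaintySpec(0.20, 0.0))
        assert rob.objective == pytest.approx(det.objective, abs=1e-9)

    def test_zero_budget_model_differs_only_in_demand_sense(self, small_instance):
        det = cv.build_static(small_instance)
        rob = cv.build_robust(small_instance, cv.UncertaintySpec(0.20, 0.0))
        assert [v.name for v in det.variables] == [v.name for v in rob.variables]
        assert det.objective == rob.objective
        assert len(det.constraints) == len(rob.constraints)
        for cd, cr in zip(det.constraints, rob.constraints):
            assert cd.coeffs == cr.coeffs and cd.rhs == cr.rhs
            if cd.name.startswith("demand["):
                assert (cd.sense, cr.sense) == ("=", ">=")
            else:
                assert cd.sense == cr.sense

    @pytest.mark.parametrize("seed", range(3))
    def test_equivalent_to_deterministic_at_inflated_demand(self, seed):
        """RHS-only uncertainty collapses the counterpart to demand inflation."""
        inst = cv.generate_instance(small_params(seed))
        unc = cv.UncertaintySpec(0.15, 0.6)
        rob = cv.solve_robust(inst, unc)
        det = cv.solve_static(
            inst, demand_rhs=cv.inflated_demand_table(inst, unc), demand_sense=">="
        )
        assert rob.objective == pytest.approx(det.objective, abs=1e-6)

    def test_objective_monotone_in_budget_and_variability(self, small_instance):
        objs = {}
        for gamma in (0.0, 0.5, 1.0):
            for delta in (0.05, 0.20):
                sol = cv.solve_robust(small_instance, cv.UncertaintySpec(delta, gamma))
                objs[(gamma, delta)] = sol.objective
        for delta in (0.05, 0.20):
            assert objs[(0.0, delta)] <= objs[(0.5, delta)] <= objs[(1.0, delta)]
        for gamma in (0.5, 1.0):
            assert objs[(gamma, 0.05)] <= objs[(gamma, 0.20)]


class TestWorstCaseOracle:
    def test_robust_plan_covers_worst_case(self, small_instance):
        unc = cv.UncertaintySpec(0.20, 1.0)
        plan = cv.solve_robust(small_instance, unc)
        report = cv.worst_case_oracle(small_instance, unc, plan)
        assert report.feasible
        assert report.worst_objective == pytest.approx(plan.objective)

    def test_deterministic_plan_fails_worst_case(self, small_instance):
        unc = cv.UncertaintySpec(0.20, 1.0)
        plan = cv.solve_static(small_instance)
        report = cv.worst_case_oracle(small_instance, unc, plan)
        assert not report.feasible
        assert report.shortfalls

    def test_zero_budget_oracle_is_nominal_check(self, small_instance):
        unc = cv.UncertaintySpec(0.20, 0.0)
        plan = cv.solve_static(small_instance)
        report = cv.worst_case_oracle(small_instance, unc, plan)
        assert report.feasible
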