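"""Data model, validation and serialization."""

import json

import pytest

import casevac as cv
from casevac.instance import instance_from_dict, instance_to_dict


class TestLushanFixture:
    def test_index_set_sizes(self, lushan):
        assert len(lushan.areas) == 9
        assert len(lushan.temp_candidates) == 5
        assert len(lushan.general_candidates) == 3

    @pytest.mark.parametrize(
        "area, severity, count",
        [("I6", cv.SERIOUS, 70), ("I1", cv.MODERATE, 143), ("I9", cv.SERIOUS, 5)],
    )
    def test_casualty_cells(self, lushan, area, severity, count):
        assert lushan.casualties.get(area, severity) == count

    def test_totals(self, lushan):
        assert lushan.casualties.total(cv.SERIOUS) == 255
        assert lushan.casualties.total(cv.MODERATE) == 730
        assert lushan.casualties.total() == 985

    def test_travel_time_cells(self, lushan):
        assert lushan.times.road_hours[("I9", "J2")] == 2.250
        assert lushan.times.road_hours[("I1", "J1")] == 1.250
        assert lushan.times.air_hours[("J2", "K3")] == 0.61

    def test_capacities_and_fleet(self, lushan):
        assert all(lushan.temp_cap(j) == 500 for j in lushan.temp_candidates)
        assert lushan.general_cap("K3", cv.MODERATE) == 500
        assert lushan.general_cap("K1", cv.SERIOUS) == 250
        assert lushan.fleet.vehicle_capacity == 6
        assert lushan.fleet.helicopter_capacity == 12
        # seat capacity must cover the 985 casualties for the case to admit
        # any plan at all
        assert lushan.fleet.n_vehicles * lushan.fleet.vehicle_capacity >= 985
        assert lushan.fleet.n_helicopters * lushan.fleet.helicopter_capacity >= 985

    def test_severity_parameters(self, lushan):
        assert lushan.severity(cv.SERIOUS).urgency_weight == 2
        assert lushan.severity(cv.MODERATE).urgency_weight == 1
        assert lushan.severity(cv.SERIOUS).base_deterioration == 0.8
        assert lushan.severity(cv.MODERATE).base_deterioration == 0.2
        assert lushan.post_treatment_factor == 0.2

    def test_validates_clean(self, lushan):
        rep = cv.validate(lushan)
        assert rep.errors == []
        assert rep.warnings == []


class TestValidation:
    def test_tight_temporary_capacity_warns(self, lushan):
        import dataclasses

        caps = dataclasses.replace(lushan.capacities)
        caps.temp_capacity = {j: 100 for j in lushan.temp_candidates}
        tight = dataclasses.replace(lushan, capacities=caps)
        rep = cv.validate(tight)
        assert rep.ok
        assert any(code == "tight-temp-capacity" for code, _ in rep.warnings)

    def test_empty_area_list_is_error(self, lushan):
        import dataclasses

        broken = dataclasses.replace(lushan, areas=[])
        rep = cv.validate(broken)
        assert not rep.ok

    def test_negative_count_rejected_on_load(self, lushan, tmp_path):
        doc = instance_to_dict(lushan)
        doc["casualties"][0]["count"] = -3
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="non-negative"):
            cv.load_instance(path)

    def test_missing_matrix_cell_rejected(self, lushan, tmp_path):
        doc = instance_to_dict(lushan)
        doc["road_times"] = doc["road_times"][1:]
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="road time"):
            cv.load_instance(path)

    def test_missing_key_names_field(self, tmp_path):
        path = tmp_path / "empty.json"
        path.write_text("{}")
        with pytest.raises(ValueError, match="casualties"):
            cv.load_instance(path)


class TestSerialization:
    def test_json_round_trip(self, lushan, tmp_path):
        path = tmp_path / "lushan.json"
        cv.save_instance(lushan, path)
        again = cv.load_instance(path)
        assert instance_to_dict(again) == instance_to_dict(lushan)

    def test_csv_bundle_round_trip(self, small_instance, tmp_path):
        d = tmp_path / "bundle"
        cv.save_csv_bundle(small_instance, d)
        again = cv.load_instance(d)
        a, b = instance_to_dict(again), instance_to_dict(small_instance)
        a.pop("name"), b.pop("name")  # bundle directories carry their own name
        assert a == b

    def test_dict_round_trip_preserves_floats(self, lushan):
        again = instance_from_dict(instance_to_dict(lushan))
        assert again.times.road_hours == lushan.times.road_hours
        assert again.times.air_hours == lushan.times.air_hours
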