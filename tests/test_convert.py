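import json
import random

import pytest

from pfb.convert import (
    from_json,
    make_blank_record,
    to_json,
    validate_records,
)
from pfb.errors import UnknownNodeError, ValidationError
from pfb.model import Entity, Relation, load_dictionary
from pfb.pfb_io import write_pfb
from pfb.schema_compiler import build_metadata, compile_schema

from conftest import make_sim_batch, write_batch
from validator_oracle import brute_force_violations


def canonical(obj):
    return json.dumps(obj, sort_keys=True)


class TestFromJson:
    def test_single_valid_record(self, demographic_dict, demographic_records):
        entities, violations = from_json(demographic_dict, demographic_records)
        assert violations == []
        assert len(entities) == 2
        assert entities[0].object["gender"] == "Not Reported"

    def test_unknown_node_key_raises(self, demographic_dict):
        with pytest.raises(UnknownNodeError):
            from_json(demographic_dict, {"visit": []})

    def test_dangling_parent_in_strict_mode(self, trio_dict):
        records = {
            "sample": [{"id": "s1", "volume": 1.0,
                        "subject": {"id": "sub_missing"}}]
        }
        with pytest.raises(ValidationError) as exc:
            from_json(trio_dict, records, strict=True)
        rules = {v.rule for v in exc.value.violations}
        assert "dangling_relation" in rules

    def test_emission_order_is_topological(self, trio_dict):
        records = {
            "sample": [{"id": "s1", "volume": 1.0, "subject": {"id": "sub1"}}],
            "subject": [{"id": "sub1", "species": "human"}],
        }
        entities, violations = from_json(trio_dict, records)
        assert violations == []
        assert [e.name for e in entities] == ["subject", "sample"]

    def test_integral_float_coerced_for_integer(self, demographic_dict):
        entities, violations = from_json(
            demographic_dict, {"demographic": [{"id": "d0", "age": 44.0}]}
        )
        assert violations == []
        assert entities[0].object["age"] == 44

    def test_fractional_number_for_integer_is_violation(self, demographic_dict):
        _, violations = from_json(
            demographic_dict, {"demographic": [{"id": "d0", "age": 44.5}]}
        )
        assert [v.rule for v in violations] == ["type"]

    def test_malformed_link_field_is_violation(self, trio_dict):
        records = {"sample": [{"id": "s1", "volume": 1.0, "subject": "sub1"}]}
        _, violations = from_json(trio_dict, records)
        assert any(v.rule == "type" and v.property == "subject"
                   for v in violations)


class TestToJson:
    def test_round_trip_canonical_equality(self, tmp_path):
        d, records, entities = make_sim_batch(seed=9, n_nodes=8,
                                              records_per_node=25)
        path = write_batch(tmp_path, d, entities)
        assert canonical(to_json(path)) == canonical(records)

    def test_metadata_only_file_gives_empty_map(self, tmp_path, demographic_dict):
        path = write_batch(tmp_path, demographic_dict, [])
        assert to_json(path) == {}

    def test_enum_value_survives_unescaped(self, tmp_path, demographic_dict,
                                           demographic_records):
        entities, _ = from_json(demographic_dict, demographic_records)
        path = write_batch(tmp_path, demographic_dict, entities)
        back = to_json(path)
        assert back["demographic"][0]["gender"] == "Not Reported"

    def test_mutual_inverse_through_pfb(self, tmp_path, demographic_dict,
                                        demographic_records):
        entities, _ = from_json(demographic_dict, demographic_records)
        path = write_batch(tmp_path, demographic_dict, entities)
        again, violations = from_json(demographic_dict, to_json(path))
        assert violations == []
        assert again == entities


class TestMakeBlankRecord:
    def test_demographic_template(self, tmp_path, demographic_dict):
        path = write_batch(tmp_path, demographic_dict, [])
        template = make_blank_record(path, "demographic")
        assert template == {
            "id": "",
            "gender": "Male",  # first declared enum value
            "age": 0,
            "bmi": None,  # nullable
            "consented": False,
            "enrollment_date": "",
            "notes": "",
        }

    def test_link_fields_present_and_empty(self, tmp_path, trio_dict):
        path = write_batch(tmp_path, trio_dict, [])
        template = make_blank_record(path, "demographic")
        assert template["subject"] is None

    def test_unknown_node(self, tmp_path, demographic_dict):
        path = write_batch(tmp_path, demographic_dict, [])
        with pytest.raises(UnknownNodeError):
            make_blank_record(path, "visit")

    def test_template_validates_when_links_optional(self, tmp_path, trio_dict):
        path = write_batch(tmp_path, trio_dict, [])
        template = make_blank_record(path, "demographic")
        _, violations = from_json(trio_dict, {"demographic": [template]})
        assert violations == []


class TestValidateRecords:
    def test_enum_violation(self, demographic_dict):
        e = Entity(id="d0", name="demographic",
                   object={"age": 1, "gender": "Other"}, relations=[])
        (v,) = validate_records(demographic_dict, [e])
        assert (v.rule, v.property) == ("enum", "gender")

    def test_multiplicity_violation_one_to_one(self, trio_dict):
        e = Entity(id="d0", name="demographic", object={},
                   relations=[Relation("sub1", "subject"),
                              Relation("sub2", "subject")])
        parents = [Entity(id=f"sub{i}", name="subject",
                          object={"species": "human"}, relations=[])
                   for i in (1, 2)]
        violations = validate_records(trio_dict, parents + [e])
        assert [v.rule for v in violations] == ["multiplicity"]

    def test_undeclared_link_is_multiplicity_violation(self, trio_dict):
        e = Entity(id="d0", name="subject", object={"species": "x"},
                   relations=[Relation("d1", "demographic")])
        other = Entity(id="d1", name="demographic", object={}, relations=[])
        violations = validate_records(trio_dict, [e, other])
        assert [v.rule for v in violations] == ["multiplicity"]

    def test_required_link_missing(self, trio_dict):
        e = Entity(id="s0", name="sample", object={"volume": 0.5}, relations=[])
        (v,) = validate_records(trio_dict, [e])
        assert (v.rule, v.property) == ("required", "subject")

    def test_fully_valid_batch(self):
        d, _, entities = make_sim_batch(seed=12)
        assert validate_records(d, entities) == []

    def test_violation_count_invariant_under_permutation(self, trio_dict):
        rng = random.Random(0)
        batch = [
            Entity(id="sub1", name="subject", object={"species": "human"},
                   relations=[]),
            Entity(id="s1", name="sample", object={"volume": "not a number"},
                   relations=[Relation("sub1", "subject")]),
            Entity(id="d1", name="demographic", object={"gender": "Nope"},
                   relations=[Relation("subX", "subject")]),
        ]
        baseline = validate_records(trio_dict, batch)
        for _ in range(5):
            shuffled = batch[:]
            rng.shuffle(shuffled)
            permuted = validate_records(trio_dict, shuffled)
            assert len(permuted) == len(baseline)
            assert sorted((v.node, v.property, v.rule) for v in permuted) == \
                sorted((v.node, v.property, v.rule) for v in baseline)

    def test_matches_brute_force_oracle_on_clean_batch(self):
        d, _, entities = make_sim_batch(seed=13)
        ours = {(v.entity_index, v.node, v.property, v.rule)
                for v in validate_records(d, entities)}
        assert ours == brute_force_violations(d, entities) == set()


def test_ndjson_dir_round_trip(tmp_path, demographic_dict, demographic_records):
    from pfb.convert import read_json_dir, write_json_dir

    write_json_dir(demographic_records, tmp_path / "nd", ndjson=True)
    assert read_json_dir(tmp_path / "nd") == demographic_records
    write_json_dir(demographic_records, tmp_path / "plain")
    assert read_json_dir(tmp_path / "plain") == demographic_records
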