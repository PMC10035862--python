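import json

import pytest
from hypothesis import HealthCheck, settings

from pfb.convert import from_json
from pfb.model import load_dictionary
from pfb.pfb_io import write_pfb
from pfb.schema_compiler import build_metadata, compile_schema
from pfb.simulator import SimConfig, simulate_dictionary, simulate_records

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


DEMOGRAPHIC_DOC = {
    "name": "demo_model",
    "version": "0.1.0",
    "nodes": [
        {
            "name": "demographic",
            "ontology_reference": "http://purl.obolibrary.org/obo/NCIT_C16495",
            "values": {"category": "clinical"},
            "properties": [
                {
                    "name": "gender",
                    "type": "enum",
                    "enum": ["Male", "Female", "Not Reported"],
                    "ontology_reference": "http://purl.obolibrary.org/obo/NCIT_C17357",
                },
                {"name": "age", "type": "integer", "required": True},
                {"name": "bmi", "type": "number", "nullable": True},
                {"name": "consented", "type": "boolean"},
                {"name": "enrollment_date", "type": "date"},
                {"name": "notes", "type": "string"},
            ],
        }
    ],
}

# subject <- demographic (ONE_TO_ONE), subject <- sample (MANY_TO_ONE, required)
TRIO_DOC = {
    "name": "trio_model",
    "version": "0.2.0",
    "nodes": [
        {
            "name": "subject",
            "ontology_reference": "http://purl.obolibrary.org/obo/NCIT_C41189",
            "properties": [{"name": "species", "type": "string"}],
        },
        {
            "name": "demographic",
            "properties": [
                {
                    "name": "gender",
                    "type": "enum",
                    "enum": ["Male", "Female", "Not Reported"],
                },
                {"name": "age", "type": "integer"},
            ],
            "links": [{"dst": "subject", "multiplicity": "ONE_TO_ONE"}],
        },
        {
            "name": "sample",
            "properties": [{"name": "volume", "type": "number"}],
            "links": [
                {"dst": "subject", "multiplicity": "MANY_TO_ONE", "required": True}
            ],
        },
    ],
}


@pytest.fixture
def demographic_dict():
    return load_dictionary(json.loads(json.dumps(DEMOGRAPHIC_DOC)))


@pytest.fixture
def trio_dict():
    return load_dictionary(json.loads(json.dumps(TRIO_DOC)))


@pytest.fixture
def demographic_records():
    return {
        "demographic": [
            {
                "id": "demographic_0",
                "gender": "Not Reported",
                "age": 44,
                "bmi": None,
                "consented": True,
                "enrollment_date": "2021-06-01",
                "notes": "enrolled at baseline",
            },
            {
                "id": "demographic_1",
                "gender": "Female",
                "age": 61,
                "bmi": 24.7,
                "consented": False,
                "enrollment_date": "2021-07-15",
                "notes": "",
            },
        ]
    }


def make_sim_batch(seed=7, n_nodes=6, attrs_per_node=4, records_per_node=10):
    """Simulated dictionary + records + converted entities, one call."""
    cfg = SimConfig(
        n_nodes=n_nodes,
        total_attributes=n_nodes * attrs_per_node,
        records_per_node=records_per_node,
        seed=seed,
    )
    d = simulate_dictionary(cfg)
    records = simulate_records(d, cfg)
    entities, violations = from_json(d, records)
    assert violations == []
    return d, records, entities


@pytest.fixture
def sim_batch():
    return make_sim_batch()


def write_batch(tmp_path, d, entities, codec="deflate", name="batch.pfb"):
    path = tmp_path / name
    write_pfb(path, compile_schema(d), build_metadata(d), entities, codec=codec)
    return path
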