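"""Synthetic Gen3-style dictionaries and record sets.

The generator emulates the kind of graph data model found in production data
commons: a rooted tree of node types (program/project/subject/...), each
carrying a mix of string, numeric, boolean, date, and enumeration properties
annotated with NCI Thesaurus-style ontology references. Defaults match the
benchmark configuration of a commons-scale model: 26 nodes carrying 399
attributes in total, 100 records per node.

Enum value pools deliberately include strings such as ``"Not Reported"`` that
are not legal Avro symbols, so the whole escape/restore path is exercised by
any simulated batch. String payloads are drawn from a small token vocabulary,
which gives the repetitive content that makes compression behave as it does
on real clinical exports.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .errors import ConfigError
from .model import (
    DataDictionary,
    LinkDef,
    Multiplicity,
    NodeDef,
    PropertyDef,
    topological_order,
)

_NODE_NAMES = [
    "program", "project", "study", "subject", "demographic", "exposure",
    "diagnosis", "comorbidity", "medication", "treatment", "follow_up",
    "lab_result", "biospecimen", "sample", "aliquot", "read_group",
    "sequencing", "imaging_study", "imaging_file", "surgery", "radiation",
    "family_history", "vital_signs", "questionnaire", "adverse_event",
    "survival",
]

_ENUM_POOL = [
    "Yes", "No", "Unknown", "Not Reported", "Male", "Female", "Positive",
    "Negative", "Stage I", "Stage II", "Stage III", "Stage IV", "Mild",
    "Moderate", "Severe", "Never", "Former", "Current", "Alive", "Dead",
    "Baseline", "Follow-Up", "Left", "Right", "Bilateral", "Not Applicable",
]

_LOREM = [
    "lorem", "ipsum", "dolor", "sit", "amet", "consectetur", "adipiscing",
    "elit", "sed", "do", "eiusmod", "tempor", "incididunt", "labore",
    "dolore", "magna", "aliqua", "enim", "minim", "veniam",
]

_SCALAR_TYPES = ["string", "integer", "number", "boolean", "date"]


@dataclass
class SimConfig:
    """Shape of a simulated study: graph size, payload size, and randomness.

    ``total_attributes`` are spread as evenly as possible over the nodes
    (every node gets at least one). ``enum_fraction`` is the probability a
    property is an enumeration; the remaining mass is uniform over the
    scalar types.
    """

    n_nodes: int = 26
    total_attributes: int = 399
    records_per_node: int = 100
    enum_fraction: float = 0.3
    max_enum_values: int = 5
    seed: int = 42

    def validate(self) -> None:
        if self.n_nodes < 1:
            raise ConfigError("n_nodes must be >= 1")
        if self.total_attributes < self.n_nodes:
            raise ConfigError("total_attributes must be >= n_nodes")
        if self.records_per_node < 0:
            raise ConfigError("records_per_node must be >= 0")
        if not 0.0 <= self.enum_fraction <= 1.0:
            raise ConfigError("enum_fraction must be in [0, 1]")
        if self.max_enum_values < 2:
            raise ConfigError("max_enum_values must be >= 2")


def _node_name(i: int) -> str:
    return _NODE_NAMES[i] if i < len(_NODE_NAMES) else f"node_{i:03d}"


def _ontology_ref(rng: random.Random) -> str:
    return f"http://purl.obolibrary.org/obo/NCIT_C{rng.randint(10000, 99999)}"


def simulate_dictionary(cfg: SimConfig) -> DataDictionary:
    """Build a valid random dictionary: a rooted tree of MANY_TO_ONE links.

    Node 0 is the root; every later node links to a uniformly chosen earlier
    node, which guarantees acyclicity and a single connected component.
    Deterministic for a fixed seed.
    """
    cfg.validate()
    rng = random.Random(cfg.seed)
    base, extra = divmod(cfg.total_attributes, cfg.n_nodes)

    nodes: list[NodeDef] = []
    for i in range(cfg.n_nodes):
        name = _node_name(i)
        n_props = base + (1 if i < extra else 0)
        props: list[PropertyDef] = []
        for j in range(n_props):
            if rng.random() < cfg.enum_fraction:
                k = rng.randint(2, cfg.max_enum_values)
                enum_values = rng.sample(_ENUM_POOL, k)
                ptype, extra_kw = "enum", {"enum_values": enum_values}
            else:
                ptype, extra_kw = rng.choice(_SCALAR_TYPES), {}
            required = rng.random() < 0.25
            nullable = (not required) and rng.random() < 0.15
            props.append(
                PropertyDef(
                    name=f"prop_{j:02d}",
                    type=ptype,
                    required=required,
                    nullable=nullable,
                    ontology_reference=_ontology_ref(rng),
                    values={
                        "ontology_reference": _ontology_ref(rng),
                        "ontology_name": "NCI Thesaurus",
                    },
                    **extra_kw,
                )
            )
        links = []
        if i > 0:
            parent = _node_name(rng.randrange(i))
            links.append(
                LinkDef(dst=parent, multiplicity=Multiplicity.MANY_TO_ONE,
                        required=True)
            )
        nodes.append(
            NodeDef(
                name=name,
                ontology_reference=_ontology_ref(rng),
                properties=props,
                links=links,
                values={"category": rng.choice(["administrative", "clinical",
                                                "biospecimen", "data_file"])},
            )
        )
    return DataDictionary(
        name=f"simulated_commons_{cfg.seed}", version="1.0.0", nodes=nodes
    )


def _value_for(p: PropertyDef, rng: random.Random):
    if p.type == "enum":
        return rng.choice(p.enum_values)
    if p.type == "string":
        return " ".join(rng.choices(_LOREM, k=rng.randint(3, 8)))
    if p.type == "integer":
        return rng.randint(0, 120)
    if p.type == "number":
        return round(rng.uniform(0.0, 100.0), 2)
    if p.type == "boolean":
        return rng.random() < 0.5
    # date
    return f"{rng.randint(1990, 2023):04d}-{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}"


def simulate_records(d: DataDictionary, cfg: SimConfig) -> dict[str, list[dict]]:
    """Populate ``records_per_node`` JSON objects for every node.

    Every property is filled with a type-valid value, ids follow the
    ``<node>_<k>`` convention, and every link points at a uniformly chosen
    existing parent id — so the output is always validator-clean.
    Deterministic for a fixed seed.
    """
    cfg.validate()
    rng = random.Random(cfg.seed * 2654435761 % (1 << 31) + 1)
    out: dict[str, list[dict]] = {}
    for name in topological_order(d):
        node = d.node(name)
        recs = []
        for k in range(cfg.records_per_node):
            rec: dict = {"id": f"{name}_{k}"}
            for p in node.properties:
                rec[p.name] = _value_for(p, rng)
            for l in node.links:
                if cfg.records_per_node > 0:
                    parent = f"{l.dst}_{rng.randrange(cfg.records_per_node)}"
                    link_val = {"id": parent}
                    rec[l.dst] = (
                        [link_val]
                        if l.multiplicity == Multiplicity.MANY_TO_MANY
                        else link_val
                    )
            recs.append(rec)
        out[name] = recs
    return out
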