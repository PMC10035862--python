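"""Domain model for PFB graph data dictionaries, entities, and metadata.

A *data dictionary* defines the node types of a graph data model: each node
carries typed properties, links to parent nodes (with a cardinality class),
and ontology references into third-party controlled vocabularies (NCIt,
SNOMED CT, ...). One data record is wrapped in an :class:`Entity`, which holds
the record id, the node name, the property payload, and :class:`Relation`
pointers to parent records.

The dictionary dialect accepted by :func:`load_dictionary` is a minimal
JSON/YAML document::

    {"name": ..., "version": ...,
     "nodes": [{"name": ..., "ontology_reference": ..., "values": {...},
                "properties": [{"name": ..., "type": "string|integer|number|boolean|enum|date",
                                "enum": [...], "required": bool, "nullable": bool,
                                "ontology_reference": ..., "values": {...}}],
                "links": [{"dst": ..., "multiplicity": "MANY_TO_ONE", "required": bool}]}]}

Links point child → parent, and the link graph must be acyclic so records can
always be emitted parents-first.
"""

from __future__ import annotations

import enum
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, IO, Mapping

import networkx as nx
import yaml

from .errors import (
    CycleError,
    DuplicateNameError,
    ParseError,
    UnresolvedLinkError,
)

PROPERTY_TYPES = ("string", "integer", "number", "boolean", "enum", "date")

VIOLATION_RULES = frozenset(
    {
        "unknown_node",
        "unknown_property",
        "type",
        "enum",
        "required",
        "multiplicity",
        "dangling_relation",
    }
)


class Multiplicity(str, enum.Enum):
    """Cardinality class of a link between a child node and its parent."""

    ONE_TO_ONE = "ONE_TO_ONE"
    ONE_TO_MANY = "ONE_TO_MANY"
    MANY_TO_ONE = "MANY_TO_ONE"
    MANY_TO_MANY = "MANY_TO_MANY"


@dataclass
class PropertyDef:
    """One typed property of a node.

    ``values`` is a free-form string map for annotations such as ontology
    URL, version, or name. ``required`` and ``nullable`` are mutually
    exclusive: a required property may never be null.
    """

    name: str
    type: str
    enum_values: list[str] = field(default_factory=list)
    required: bool = False
    nullable: bool = False
    ontology_reference: str = ""
    values: dict[str, str] = field(default_factory=dict)


@dataclass
class LinkDef:
    """A link from the declaring (child) node to the ``dst`` (parent) node."""

    dst: str
    multiplicity: Multiplicity = Multiplicity.MANY_TO_ONE
    required: bool = False


@dataclass
class NodeDef:
    name: str
    ontology_reference: str = ""
    properties: list[PropertyDef] = field(default_factory=list)
    links: list[LinkDef] = field(default_factory=list)
    values: dict[str, str] = field(default_factory=dict)

    def property(self, name: str) -> PropertyDef | None:
        for p in self.properties:
            if p.name == name:
                return p
        return None

    def link(self, dst: str) -> LinkDef | None:
        for l in self.links:
            if l.dst == dst:
                return l
        return None


@dataclass
class DataDictionary:
    """A named, versioned graph data model: an acyclic set of node types."""

    name: str = ""
    version: str = ""
    nodes: list[NodeDef] = field(default_factory=list)

    def node(self, name: str) -> NodeDef | None:
        for n in self.nodes:
            if n.name == name:
                return n
        return None

    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def to_mapping(self) -> dict:
        """Serialize back to the dictionary dialect (inverse of load)."""
        nodes = []
        for n in self.nodes:
            props = []
            for p in n.properties:
                d: dict[str, Any] = {"name": p.name, "type": p.type}
                if p.type == "enum":
                    d["enum"] = list(p.enum_values)
                if p.required:
                    d["required"] = True
                if p.nullable:
                    d["nullable"] = True
                if p.ontology_reference:
                    d["ontology_reference"] = p.ontology_reference
                if p.values:
                    d["values"] = dict(p.values)
                props.append(d)
            links = []
            for l in n.links:
                ld: dict[str, Any] = {"dst": l.dst, "multiplicity": l.multiplicity.value}
                if l.required:
                    ld["required"] = True
                links.append(ld)
            nd: dict[str, Any] = {"name": n.name, "properties": props}
            if n.ontology_reference:
                nd["ontology_reference"] = n.ontology_reference
            if n.values:
                nd["values"] = dict(n.values)
            if links:
                nd["links"] = links
            nodes.append(nd)
        return {"name": self.name, "version": self.version, "nodes": nodes}

    def dumps(self) -> str:
        return json.dumps(self.to_mapping(), indent=2)


@dataclass
class Relation:
    """A pointer from a child record to a parent record."""

    dst_id: str
    dst_name: str


@dataclass
class Entity:
    """One data record: id, node name, property payload, parent relations."""

    id: str | None
    name: str
    object: dict[str, Any] = field(default_factory=dict)
    relations: list[Relation] = field(default_factory=list)


@dataclass
class PropertyMetadata:
    ontology_reference: str = ""
    values: dict[str, str] = field(default_factory=dict)


@dataclass
class NodeMetadata:
    ontology_reference: str = ""
    values: dict[str, str] = field(default_factory=dict)
    properties: dict[str, PropertyMetadata] = field(default_factory=dict)
    links: list[LinkDef] = field(default_factory=list)


@dataclass
class MetadataBlock:
    """Per-node / per-property ontology references stored inside the file."""

    nodes: dict[str, NodeMetadata] = field(default_factory=dict)
    misc: dict[str, str] = field(default_factory=dict)


@dataclass
class Violation:
    """One validation failure; ``rule`` is drawn from VIOLATION_RULES."""

    entity_index: int
    node: str
    property: str
    rule: str
    message: str

    def __post_init__(self):
        assert self.rule in VIOLATION_RULES, self.rule


# ---------------------------------------------------------------------------
# Dictionary loading


def _is_identifier(s: Any) -> bool:
    return (
        isinstance(s, str)
        and bool(s)
        and (s[0].isalpha() or s[0] == "_")
        and all(c.isalnum() or c == "_" for c in s)
    )


def _parse_property(raw: Any, node_name: str) -> PropertyDef:
    if not isinstance(raw, Mapping):
        raise ParseError(f"node {node_name!r}: property entry is not a mapping")
    name = raw.get("name")
    if not _is_identifier(name):
        raise ParseError(f"node {node_name!r}: invalid property name {name!r}")
    ptype = raw.get("type")
    if ptype not in PROPERTY_TYPES:
        raise ParseError(
            f"property {node_name}.{name}: type {ptype!r} not one of {PROPERTY_TYPES}"
        )
    enum_values = raw.get("enum", raw.get("enum_values", []))
    if ptype == "enum":
        if (
            not isinstance(enum_values, list)
            or not enum_values
            or not all(isinstance(v, str) and v for v in enum_values)
        ):
            raise ParseError(
                f"property {node_name}.{name}: enum requires a non-empty list of values"
            )
        if len(set(enum_values)) != len(enum_values):
            raise ParseError(f"property {node_name}.{name}: duplicate enum values")
    elif enum_values:
        raise ParseError(
            f"property {node_name}.{name}: enum values given for non-enum type"
        )
    required = bool(raw.get("required", False))
    nullable = bool(raw.get("nullable", False))
    if required and nullable:
        raise ParseError(
            f"property {node_name}.{name}: required implies not nullable"
        )
    values = raw.get("values", {}) or {}
    if not isinstance(values, Mapping) or not all(
        isinstance(k, str) and isinstance(v, str) for k, v in values.items()
    ):
        raise ParseError(f"property {node_name}.{name}: values must map str->str")
    return PropertyDef(
        name=name,
        type=ptype,
        enum_values=list(enum_values) if ptype == "enum" else [],
        required=required,
        nullable=nullable,
        ontology_reference=str(raw.get("ontology_reference", "") or ""),
        values=dict(values),
    )


def _parse_link(raw: Any, node_name: str) -> LinkDef:
    if not isinstance(raw, Mapping) or "dst" not in raw:
        raise ParseError(f"node {node_name!r}: link entry needs a 'dst'")
    token = raw.get("multiplicity", "MANY_TO_ONE")
    try:
        mult = Multiplicity(token)
    except ValueError:
        raise ParseError(
            f"node {node_name!r}: invalid multiplicity token {token!r}"
        ) from None
    return LinkDef(dst=raw["dst"], multiplicity=mult, required=bool(raw.get("required", False)))


def load_dictionary(source: str | Path | Mapping | IO[str]) -> DataDictionary:
    """Load and validate a data dictionary from JSON/YAML text, path, or mapping.

    Raises ParseError for malformed documents, DuplicateNameError for name
    clashes, UnresolvedLinkError for dangling link destinations, and
    CycleError if the link graph is not acyclic.
    """
    if isinstance(source, Mapping):
        doc: Any = source
    else:
        if isinstance(source, Path):
            text = source.read_text()
        elif isinstance(source, str):
            p = Path(source)
            # heuristically treat short extension-bearing strings as paths
            if "\n" not in source and p.suffix in (".json", ".yaml", ".yml"):
                if not p.exists():
                    raise ParseError(f"dictionary file not found: {source}")
                text = p.read_text()
            else:
                text = source
        elif isinstance(source, io.IOBase) or hasattr(source, "read"):
            text = source.read()
        else:
            raise ParseError(f"cannot load a dictionary from {type(source).__name__}")
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as e:
            raise ParseError(f"dictionary document is not valid JSON/YAML: {e}") from e

    if not isinstance(doc, Mapping):
        raise ParseError("dictionary document must be a mapping at top level")
    raw_nodes = doc.get("nodes")
    if not isinstance(raw_nodes, list) or not raw_nodes:
        raise ParseError("dictionary must declare a non-empty 'nodes' list")

    nodes: list[NodeDef] = []
    for raw in raw_nodes:
        if not isinstance(raw, Mapping):
            raise ParseError("each node must be a mapping")
        name = raw.get("name")
        if not _is_identifier(name):
            raise ParseError(f"invalid node name {name!r}")
        props = [_parse_property(p, name) for p in raw.get("properties", [])]
        pnames = [p.name for p in props]
        if len(set(pnames)) != len(pnames):
            raise DuplicateNameError(f"node {name!r}: duplicate property names")
        if "id" in pnames:
            raise ParseError(
                f"node {name!r}: 'id' is reserved for the record identifier"
            )
        links = [_parse_link(l, name) for l in raw.get("links", [])]
        dsts = [l.dst for l in links]
        if len(set(dsts)) != len(dsts):
            raise DuplicateNameError(f"node {name!r}: duplicate link destinations")
        clash = set(pnames) & set(dsts)
        if clash:
            raise ParseError(
                f"node {name!r}: names {sorted(clash)} used for both a property "
                "and a link destination (ambiguous in JSON records)"
            )
        values = raw.get("values", {}) or {}
        if not isinstance(values, Mapping):
            raise ParseError(f"node {name!r}: values must be a mapping")
        nodes.append(
            NodeDef(
                name=name,
                ontology_reference=str(raw.get("ontology_reference", "") or ""),
                properties=props,
                links=links,
                values={str(k): str(v) for k, v in values.items()},
            )
        )

    names = [n.name for n in nodes]
    if len(set(names)) != len(names):
        dupes = sorted({x for x in names if names.count(x) > 1})
        raise DuplicateNameError(f"duplicate node names: {dupes}")
    known = set(names)
    for n in nodes:
        for l in n.links:
            if l.dst not in known:
                raise UnresolvedLinkError(
                    f"node {n.name!r} links to unknown node {l.dst!r}"
                )

    d = DataDictionary(
        name=str(doc.get("name", "") or ""),
        version=str(doc.get("version", "") or ""),
        nodes=nodes,
    )
    _check_acyclic(d)
    return d


def _link_graph(d: DataDictionary) -> nx.DiGraph:
    """Directed graph with edges parent -> child (link dst -> declaring node)."""
    g = nx.DiGraph()
    g.add_nodes_from(d.node_names)
    for n in d.nodes:
        for l in n.links:
            g.add_edge(l.dst, n.name)
    return g


def _check_acyclic(d: DataDictionary) -> None:
    g = _link_graph(d)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        path = " -> ".join(str(e[0]) for e in cycle) + f" -> {cycle[-1][1]}"
        raise CycleError(f"link graph contains a cycle: {path}")


def topological_order(d: DataDictionary) -> list[str]:
    """Node names ordered so every link destination (parent) precedes its child.

    Ties are broken by declaration order in the dictionary, making the result
    deterministic for a fixed input.
    """
    index = {name: i for i, name in enumerate(d.node_names)}
    g = _link_graph(d)
    return list(nx.lexicographical_topological_sort(g, key=lambda n: index[n]))
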