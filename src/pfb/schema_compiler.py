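"""Compile a data dictionary into the self-describing PFB serialization schema.

The compiled schema is a standard Avro record named ``Entity``::

    Entity { id: null|string, name: string,
             object: union[Metadata, <one record per node>],
             relations: array<Relation> }

``Metadata`` is always the first union branch; it stores, for every node and
property, the ontology reference and free-form annotation values, plus the
link structure of the graph — so a PFB file fully describes its own data
model. Property flags that Avro cannot express (required/nullable, the date
annotation) travel as custom attributes (``pfb_required``, ``pfb_nullable``,
``pfb_format``) which conforming Avro readers ignore.

Enum values that are not legal Avro symbols (e.g. ``"Not Reported"``) are
escaped with an injective ``_xHH_`` scheme, so the original strings are
recoverable without an external lookup table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import cached_property
from typing import Any

from . import avro
from .errors import (
    EmptyDictionaryError,
    NameCollisionError,
    NotPFBError,
    UnknownTypeError,
)
from .model import (
    DataDictionary,
    LinkDef,
    MetadataBlock,
    Multiplicity,
    NodeDef,
    NodeMetadata,
    PropertyDef,
    PropertyMetadata,
)

#: Type names claimed by the PFB envelope itself; dictionary nodes may not use them.
RESERVED_NAMES = frozenset(
    {"Entity", "Metadata", "Node", "Property", "Link", "Relation", "Multiplicity"}
)

_AVRO_TYPE = {
    "string": "string",
    "integer": "long",
    "number": "double",
    "boolean": "boolean",
}


# ---------------------------------------------------------------------------
# Enum symbol sanitization


def _is_plain(c: str) -> bool:
    return ("a" <= c <= "z") or ("A" <= c <= "Z") or ("0" <= c <= "9")


def sanitize_enum_symbol(value: str) -> tuple[str, bool]:
    """Escape an enum value into a legal Avro symbol.

    Every character outside ``[A-Za-z0-9]`` (and a leading digit) is replaced
    by ``_x<hex codepoint>_``. Because a raw ``_`` is itself escaped, every
    underscore in the output delimits an escape, which makes the mapping
    injective over *all* strings — two distinct values can never collide.
    Returns ``(symbol, reversible)``; reversibility always holds under this
    scheme.
    """
    if not value:
        raise ValueError("enum value must be non-empty")
    out = []
    for i, c in enumerate(value):
        if _is_plain(c) and not (i == 0 and c.isdigit()):
            out.append(c)
        else:
            out.append(f"_x{ord(c):02x}_")
    return "".join(out), True


def unsanitize_enum_symbol(symbol: str) -> str:
    """Invert :func:`sanitize_enum_symbol`."""
    out = []
    i = 0
    while i < len(symbol):
        if symbol[i] == "_":
            j = symbol.index("_", i + 2)  # skip the 'x'
            out.append(chr(int(symbol[i + 2 : j], 16)))
            i = j + 1
        else:
            out.append(symbol[i])
            i += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# Type mapping


def map_property_type(prop: PropertyDef, enum_name: str | None = None) -> Any:
    """Map one property definition to an Avro schema type node.

    string→string, integer→long, number→double, boolean→boolean, date→string
    carrying a ``pfb_format: date`` annotation, enum→Avro enum with sanitized
    symbols. A nullable property is wrapped in a ``["null", T]`` union.
    """
    t = prop.type
    if t in _AVRO_TYPE:
        base: Any = _AVRO_TYPE[t]
    elif t == "date":
        base = {"type": "string", "pfb_format": "date"}
    elif t == "enum":
        symbols = [sanitize_enum_symbol(v)[0] for v in prop.enum_values]
        if len(set(symbols)) != len(symbols):  # unreachable: escape is injective
            raise NameCollisionError(
                f"enum symbols collide for property {prop.name!r}"
            )
        base = {
            "type": "enum",
            "name": enum_name or f"{prop.name}_values",
            "symbols": symbols,
        }
    else:
        raise UnknownTypeError(f"property {prop.name!r} has unknown type {t!r}")
    if prop.nullable:
        return ["null", base]
    return base


def _field_for(prop: PropertyDef, enum_name: str) -> dict:
    """Build the Avro field for a property.

    Any non-required property is null-wrapped on the wire so that *absence*
    is encodable; the original required/nullable flags ride along as custom
    attributes.
    """
    base = map_property_type(
        PropertyDef(
            name=prop.name,
            type=prop.type,
            enum_values=prop.enum_values,
        ),
        enum_name=enum_name,
    )
    f: dict[str, Any] = {"name": prop.name}
    if prop.required:
        f["type"] = base
    else:
        f["type"] = ["null", base]
        f["default"] = None
    f["pfb_required"] = prop.required
    f["pfb_nullable"] = prop.nullable
    return f


# ---------------------------------------------------------------------------
# The Metadata envelope schema (paper-style Node/Property/Link records)


def _metadata_record() -> dict:
    link = {
        "type": "record",
        "name": "Link",
        "fields": [
            {
                "name": "multiplicity",
                "type": {
                    "type": "enum",
                    "name": "Multiplicity",
                    "symbols": [m.value for m in Multiplicity],
                },
            },
            {"name": "dst", "type": "string"},
            {"name": "required", "type": "boolean", "default": False},
        ],
    }
    prop = {
        "type": "record",
        "name": "Property",
        "fields": [
            {"name": "name", "type": "string"},
            {"name": "ontology_reference", "type": "string"},
            {"name": "values", "type": {"type": "map", "values": "string"}},
        ],
    }
    node = {
        "type": "record",
        "name": "Node",
        "fields": [
            {"name": "name", "type": "string"},
            {"name": "ontology_reference", "type": "string"},
            {"name": "values", "type": {"type": "map", "values": "string"}},
            {"name": "links", "type": {"type": "array", "items": link}},
            {"name": "properties", "type": {"type": "array", "items": prop}},
        ],
    }
    return {
        "type": "record",
        "name": "Metadata",
        "fields": [
            {"name": "nodes", "type": {"type": "array", "items": node}},
            {"name": "misc", "type": {"type": "map", "values": "string"}},
        ],
    }


def _relation_record() -> dict:
    return {
        "type": "record",
        "name": "Relation",
        "fields": [
            {"name": "dst_id", "type": "string"},
            {"name": "dst_name", "type": "string"},
        ],
    }


# ---------------------------------------------------------------------------
# PFBSchema


@dataclass
class PFBSchema:
    """The compiled serialization schema plus derived lookup tables."""

    document: dict
    node_records: dict[str, dict] = field(default_factory=dict)
    enum_symbols: dict[str, dict[str, dict[str, str]]] = field(default_factory=dict)

    @cached_property
    def parsed(self) -> avro.Schema:
        return avro.Schema(self.document)

    @property
    def node_names(self) -> list[str]:
        return list(self.node_records)

    @property
    def branch_names(self) -> list[str]:
        return ["Metadata"] + self.node_names

    def canonical_document(self) -> str:
        """Deterministic byte representation of the schema document."""
        return json.dumps(self.document, sort_keys=True, separators=(",", ":"))

    def canonical_form(self) -> str:
        """Avro Parsing Canonical Form of the schema."""
        return avro.canonical_form(self.document)

    def fields_of(self, node: str) -> list[dict]:
        return self.node_records[node]["fields"]

    @classmethod
    def from_document(cls, document: dict) -> "PFBSchema":
        """Rebuild a PFBSchema from a schema document read out of a file."""
        if (
            not isinstance(document, dict)
            or document.get("name", "").split(".")[-1] != "Entity"
        ):
            raise NotPFBError("container schema is not a PFB Entity schema")
        fields = {f["name"]: f for f in document.get("fields", [])}
        if not {"id", "name", "object", "relations"} <= set(fields):
            raise NotPFBError("Entity schema lacks the PFB fields")
        branches = fields["object"]["type"]
        if not isinstance(branches, list) or not branches:
            raise NotPFBError("Entity.object is not a union")
        names = [b.get("name", "").split(".")[-1] for b in branches]
        if names[0] != "Metadata":
            raise NotPFBError("first Entity.object branch is not Metadata")
        node_records = {n: b for n, b in zip(names[1:], branches[1:])}
        schema = cls(document=document, node_records=node_records)
        for node, rec in node_records.items():
            for f in rec.get("fields", []):
                inner, _ = unwrap_field_type(f["type"])
                if isinstance(inner, dict) and inner.get("type") == "enum":
                    schema.enum_symbols.setdefault(node, {})[f["name"]] = {
                        unsanitize_enum_symbol(s): s for s in inner["symbols"]
                    }
        return schema


def unwrap_field_type(ftype: Any) -> tuple[Any, bool]:
    """Strip the optional ``["null", T]`` wrapper; returns (inner, optional)."""
    if isinstance(ftype, list):
        inner = [b for b in ftype if b != "null"]
        if len(inner) != 1:
            raise NotPFBError(f"unsupported union shape in node record: {ftype!r}")
        return inner[0], True
    return ftype, False


# ---------------------------------------------------------------------------
# Compilation


def compile_schema(d: DataDictionary) -> PFBSchema:
    """Compile a valid dictionary into its PFB Avro schema.

    The Entity.object union gets one branch per node plus the leading
    Metadata branch. Raises EmptyDictionaryError for a node-less dictionary
    and NameCollisionError when a node uses a reserved envelope name or two
    generated enum type names collide.
    """
    if not d.nodes:
        raise EmptyDictionaryError("cannot compile a dictionary with no nodes")
    used_names: set[str] = set(RESERVED_NAMES)
    for n in d.nodes:
        if n.name in RESERVED_NAMES:
            raise NameCollisionError(
                f"node name {n.name!r} is reserved by the PFB envelope"
            )
        used_names.add(n.name)

    node_records: dict[str, dict] = {}
    enum_symbols: dict[str, dict[str, dict[str, str]]] = {}
    for n in d.nodes:
        fields = []
        for p in n.properties:
            enum_name = f"{n.name}_{p.name}_values"
            if p.type == "enum":
                if enum_name in used_names:
                    raise NameCollisionError(
                        f"sanitized enum type name {enum_name!r} collides"
                    )
                used_names.add(enum_name)
                enum_symbols.setdefault(n.name, {})[p.name] = {
                    v: sanitize_enum_symbol(v)[0] for v in p.enum_values
                }
            fields.append(_field_for(p, enum_name))
        node_records[n.name] = {"type": "record", "name": n.name, "fields": fields}

    document = {
        "type": "record",
        "name": "Entity",
        "fields": [
            {"name": "id", "type": ["null", "string"], "default": None},
            {"name": "name", "type": "string"},
            {
                "name": "object",
                "type": [_metadata_record()] + [node_records[n.name] for n in d.nodes],
            },
            {
                "name": "relations",
                "type": {"type": "array", "items": _relation_record()},
                "default": [],
            },
        ],
    }
    schema = PFBSchema(
        document=document, node_records=node_records, enum_symbols=enum_symbols
    )
    schema.parsed  # validate eagerly: any inconsistency fails at compile time
    return schema


def build_metadata(d: DataDictionary) -> MetadataBlock:
    """Build the in-file metadata block mirroring the dictionary structure."""
    nodes: dict[str, NodeMetadata] = {}
    for n in d.nodes:
        nodes[n.name] = NodeMetadata(
            ontology_reference=n.ontology_reference,
            values=dict(n.values),
            properties={
                p.name: PropertyMetadata(
                    ontology_reference=p.ontology_reference, values=dict(p.values)
                )
                for p in n.properties
            },
            links=[LinkDef(l.dst, l.multiplicity, l.required) for l in n.links],
        )
    return MetadataBlock(nodes=nodes, misc={"name": d.name, "version": d.version})


def dictionary_from_parts(schema: PFBSchema, metadata: MetadataBlock) -> DataDictionary:
    """Reconstruct the data dictionary from a file's schema + metadata block.

    Inverse of ``compile_schema`` + ``build_metadata``: property types come
    from the Avro fields (with their pfb_* annotations), ontology references,
    annotation values and links come from the metadata block.
    """
    nodes: list[NodeDef] = []
    for name, rec in schema.node_records.items():
        meta = metadata.nodes.get(name, NodeMetadata())
        props: list[PropertyDef] = []
        for f in rec.get("fields", []):
            inner, optional = unwrap_field_type(f["type"])
            required = bool(f.get("pfb_required", not optional))
            nullable = bool(f.get("pfb_nullable", False))
            enum_values: list[str] = []
            if isinstance(inner, dict) and inner.get("type") == "enum":
                ptype = "enum"
                enum_values = [unsanitize_enum_symbol(s) for s in inner["symbols"]]
            elif isinstance(inner, dict) and inner.get("pfb_format") == "date":
                ptype = "date"
            elif inner == "string" or (
                isinstance(inner, dict) and inner.get("type") == "string"
            ):
                ptype = "string"
            elif inner == "long" or inner == "int":
                ptype = "integer"
            elif inner in ("double", "float"):
                ptype = "number"
            elif inner == "boolean":
                ptype = "boolean"
            else:
                raise NotPFBError(f"unsupported field type in node record: {inner!r}")
            pmeta = meta.properties.get(f["name"], PropertyMetadata())
            props.append(
                PropertyDef(
                    name=f["name"],
                    type=ptype,
                    enum_values=enum_values,
                    required=required,
                    nullable=nullable,
                    ontology_reference=pmeta.ontology_reference,
                    values=dict(pmeta.values),
                )
            )
        nodes.append(
            NodeDef(
                name=name,
                ontology_reference=meta.ontology_reference,
                properties=props,
                links=[LinkDef(l.dst, l.multiplicity, l.required) for l in meta.links],
                values=dict(meta.values),
            )
        )
    return DataDictionary(
        name=metadata.misc.get("name", ""),
        version=metadata.misc.get("version", ""),
        nodes=nodes,
    )
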