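"""Read and write PFB files (Avro object container files, metadata first).

A PFB file is a standard Avro object container whose records are all of type
``Entity``. The first record is always the Metadata entity carrying ontology
references and the graph structure; data entities follow in writer order.
Property payloads are stored with their node's record type: enum values are
escaped to Avro symbols on the way in and restored on the way out, so callers
only ever see the original strings.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from . import avro
from .errors import (
    CorruptFileError,
    NotPFBError,
    SchemaError,
    SchemaMismatchError,
    StrictOrderError,
)
from .model import (
    Entity,
    LinkDef,
    MetadataBlock,
    Multiplicity,
    NodeMetadata,
    PropertyMetadata,
    Relation,
)
from .schema_compiler import PFBSchema, unwrap_field_type

DEFAULT_CODEC = "deflate"


@dataclass
class _NodeCodec:
    """Per-node lookup tables shared by the encode and decode paths."""

    field_names: list[str]
    required: set[str]
    nullable: set[str]
    enum_encode: dict[str, dict[str, str]]  # prop -> {original -> symbol}
    enum_decode: dict[str, dict[str, str]]  # prop -> {symbol -> original}


def _codecs_for(schema: PFBSchema) -> dict[str, _NodeCodec]:
    out: dict[str, _NodeCodec] = {}
    for node, rec in schema.node_records.items():
        names, req, nul = [], set(), set()
        for f in rec.get("fields", []):
            _, optional = unwrap_field_type(f["type"])
            names.append(f["name"])
            if f.get("pfb_required", not optional):
                req.add(f["name"])
            if f.get("pfb_nullable", False):
                nul.add(f["name"])
        enc = schema.enum_symbols.get(node, {})
        dec = {p: {s: v for v, s in m.items()} for p, m in enc.items()}
        out[node] = _NodeCodec(names, req, nul, enc, dec)
    return out


# ---------------------------------------------------------------------------
# Metadata block <-> Avro datum


def _metadata_to_datum(metadata: MetadataBlock) -> dict:
    return {
        "nodes": [
            {
                "name": name,
                "ontology_reference": nm.ontology_reference,
                "values": dict(nm.values),
                "links": [
                    {
                        "multiplicity": l.multiplicity.value,
                        "dst": l.dst,
                        "required": l.required,
                    }
                    for l in nm.links
                ],
                "properties": [
                    {
                        "name": pname,
                        "ontology_reference": pm.ontology_reference,
                        "values": dict(pm.values),
                    }
                    for pname, pm in nm.properties.items()
                ],
            }
            for name, nm in metadata.nodes.items()
        ],
        "misc": dict(metadata.misc),
    }


def _datum_to_metadata(datum: dict) -> MetadataBlock:
    nodes: dict[str, NodeMetadata] = {}
    for n in datum.get("nodes", []):
        nodes[n["name"]] = NodeMetadata(
            ontology_reference=n.get("ontology_reference", ""),
            values=dict(n.get("values", {})),
            properties={
                p["name"]: PropertyMetadata(
                    ontology_reference=p.get("ontology_reference", ""),
                    values=dict(p.get("values", {})),
                )
                for p in n.get("properties", [])
            },
            links=[
                LinkDef(
                    dst=l["dst"],
                    multiplicity=Multiplicity(l["multiplicity"]),
                    required=bool(l.get("required", False)),
                )
                for l in n.get("links", [])
            ],
        )
    return MetadataBlock(nodes=nodes, misc=dict(datum.get("misc", {})))


# ---------------------------------------------------------------------------
# Entity <-> Avro datum


def _entity_to_datum(e: Entity, codecs: dict[str, _NodeCodec]) -> dict:
    nc = codecs.get(e.name)
    if nc is None:
        raise SchemaMismatchError(f"entity names unknown node {e.name!r}")
    declared = set(nc.field_names)
    undeclared = set(e.object) - declared
    if undeclared:
        raise SchemaMismatchError(
            f"entity of node {e.name!r} carries undeclared properties "
            f"{sorted(undeclared)}"
        )
    obj: dict = {}
    for fname in nc.field_names:
        if fname in e.object:
            value = e.object[fname]
            if value is not None and fname in nc.enum_encode:
                try:
                    value = nc.enum_encode[fname][value]
                except KeyError:
                    raise SchemaMismatchError(
                        f"{e.name}.{fname}: {value!r} is not a declared enum value"
                    ) from None
        else:
            if fname in nc.required:
                raise SchemaMismatchError(
                    f"entity of node {e.name!r} misses required property {fname!r}"
                )
            value = None
        obj[fname] = value
    if e.id is not None and not isinstance(e.id, str):
        raise SchemaMismatchError(f"entity id must be a string, got {e.id!r}")
    return {
        "id": e.id,
        "name": e.name,
        "object": avro.Branch(e.name, obj),
        "relations": [{"dst_id": r.dst_id, "dst_name": r.dst_name} for r in e.relations],
    }


def _datum_to_entity(datum: dict, codecs: dict[str, _NodeCodec]) -> Entity:
    name = datum["name"]
    nc = codecs[name]
    raw = datum["object"]
    obj: dict = {}
    for fname in nc.field_names:
        value = raw.get(fname)
        if value is None:
            if fname in nc.nullable:
                obj[fname] = None
            # plain absence is not materialized
            continue
        if fname in nc.enum_decode:
            value = nc.enum_decode[fname][value]
        obj[fname] = value
    return Entity(
        id=datum.get("id"),
        name=name,
        object=obj,
        relations=[
            Relation(dst_id=r["dst_id"], dst_name=r["dst_name"])
            for r in datum.get("relations", [])
        ],
    )


# ---------------------------------------------------------------------------
# Public API


def write_pfb(
    path: str | Path,
    schema: PFBSchema,
    metadata: MetadataBlock,
    entities: Iterable[Entity],
    codec: str = DEFAULT_CODEC,
    strict_order: bool = False,
) -> int:
    """Write a PFB file; returns the number of *data* entities written.

    The Metadata entity is always emitted first. With ``strict_order`` every
    relation must point at a (node, id) pair already written — the
    parent-before-child discipline bulk importers rely on.
    """
    codecs = _codecs_for(schema)
    meta_datum = {
        "id": None,
        "name": "Metadata",
        "object": avro.Branch("Metadata", _metadata_to_datum(metadata)),
        "relations": [],
    }
    seen: set[tuple[str, str]] = set()
    count = 0
    path = os.fspath(path)
    with open(path, "wb") as fo:
        writer = avro.ContainerWriter(fo, schema.parsed, codec=codec)
        writer.append(meta_datum)
        try:
            for e in entities:
                if strict_order:
                    for r in e.relations:
                        if (r.dst_name, r.dst_id) not in seen:
                            raise StrictOrderError(
                                f"entity {e.id!r} of {e.name!r} references "
                                f"{r.dst_name}/{r.dst_id} before it was written"
                            )
                try:
                    writer.append(_entity_to_datum(e, codecs))
                except SchemaError as err:
                    raise SchemaMismatchError(
                        f"entity {e.id!r} of node {e.name!r} fails the schema: {err}"
                    ) from err
                if strict_order and e.id is not None:
                    seen.add((e.name, e.id))
                count += 1
        finally:
            writer.close()
    return count


def _open_reader(path: str | Path):
    fo = open(os.fspath(path), "rb")
    try:
        reader = avro.ContainerReader(fo)
    except CorruptFileError:
        fo.close()
        raise
    return fo, reader


def read_metadata(path: str | Path) -> tuple[PFBSchema, MetadataBlock]:
    """Recover the compiled schema (container header) and metadata (record 0)."""
    fo, reader = _open_reader(path)
    with fo:
        schema = PFBSchema.from_document(reader.schema_json)
        first = next(iter(reader), None)
        if first is None:
            raise NotPFBError("container holds no records (metadata entity missing)")
        if first.get("name") != "Metadata":
            raise NotPFBError(
                f"first record is a {first.get('name')!r} entity, not Metadata"
            )
        return schema, _datum_to_metadata(first["object"])


def read_entities(
    path: str | Path, node_filter: set[str] | None = None
) -> Iterator[Entity]:
    """Yield the data entities of a PFB file in file order.

    The metadata entity is consumed and checked (NotPFBError if it is not the
    first record, or if a second one appears) but never yielded.
    ``node_filter`` restricts the stream to the given node names.
    """
    fo, reader = _open_reader(path)
    with fo:
        schema = PFBSchema.from_document(reader.schema_json)
        codecs = _codecs_for(schema)
        for i, datum in enumerate(reader):
            name = datum.get("name")
            if i == 0:
                if name != "Metadata":
                    raise NotPFBError(
                        f"first record is a {name!r} entity, not Metadata"
                    )
                continue
            if name == "Metadata":
                raise NotPFBError("file contains more than one Metadata record")
            if name not in codecs:
                raise NotPFBError(f"record {i} names unknown node {name!r}")
            if node_filter is not None and name not in node_filter:
                continue
            yield _datum_to_entity(datum, codecs)
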