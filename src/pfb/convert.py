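"""Convert per-node JSON record sets to/from PFB and validate them.

JSON record convention: one list of objects per node. Within an object,
``"id"`` holds the record identifier, property names hold property values,
and each link is a field named after the *destination node* holding
``{"id": <parent id>}`` — or a list of such objects for a MANY_TO_MANY link.

Canonical form (what ``to_json`` emits and round-trips exactly):

* nullable properties are always present (possibly ``null``);
* optional non-nullable properties are simply absent when unset;
* empty link fields are omitted.
"""

from __future__ import annotations

import json
from collections import Counter
from pathlib import Path
from typing import Any, Iterable

from .errors import UnknownNodeError, ValidationError
from .model import (
    DataDictionary,
    Entity,
    Multiplicity,
    Relation,
    Violation,
    topological_order,
)
from .pfb_io import read_entities, read_metadata
from .schema_compiler import dictionary_from_parts

LONG_MIN = -(1 << 63)
LONG_MAX = (1 << 63) - 1


# ---------------------------------------------------------------------------
# JSON -> entities


def _parse_link_value(value: Any) -> list[str] | None:
    """Extract parent ids from a JSON link field; None signals a bad shape."""
    if value is None:
        return []
    if isinstance(value, dict):
        value = [value]
    if not isinstance(value, list):
        return None
    ids = []
    for item in value:
        if not isinstance(item, dict) or not isinstance(item.get("id"), str):
            return None
        ids.append(item["id"])
    return ids


def from_json(
    d: DataDictionary,
    records: dict[str, list[dict]],
    strict: bool = False,
) -> tuple[list[Entity], list[Violation]]:
    """Convert per-node JSON objects into entities, topologically ordered.

    Returns ``(entities, violations)``. In strict mode any violation raises
    :class:`ValidationError` (carrying the full list) before anything is
    returned, so nothing half-converted can reach a writer.
    """
    unknown = set(records) - set(d.node_names)
    if unknown:
        raise UnknownNodeError(f"records given for unknown node(s) {sorted(unknown)}")

    entities: list[Entity] = []
    build_violations: list[Violation] = []
    for node_name in topological_order(d):
        node = d.node(node_name)
        link_dsts = {l.dst for l in node.links}
        nullable = {p.name for p in node.properties if p.nullable}
        for obj in records.get(node_name, []):
            idx = len(entities)
            rec_id = obj.get("id")
            if rec_id is not None and not isinstance(rec_id, str):
                build_violations.append(
                    Violation(idx, node_name, "id", "type",
                              f"record id must be a string, got {rec_id!r}")
                )
                rec_id = None
            payload: dict[str, Any] = {}
            relations: list[Relation] = []
            for key, value in obj.items():
                if key == "id":
                    continue
                if key in link_dsts:
                    ids = _parse_link_value(value)
                    if ids is None:
                        build_violations.append(
                            Violation(idx, node_name, key, "type",
                                      f"link field {key!r} must hold "
                                      '{"id": ...} or a list thereof')
                        )
                        continue
                    relations.extend(Relation(dst_id=i, dst_name=key) for i in ids)
                else:
                    if isinstance(value, float) and value.is_integer():
                        p = node.property(key)
                        if p is not None and p.type == "integer":
                            value = int(value)
                    payload[key] = value
            for name in nullable - set(payload):
                payload[name] = None
            entities.append(
                Entity(id=rec_id, name=node_name, object=payload, relations=relations)
            )

    violations = build_violations + validate_records(d, entities)
    violations.sort(key=lambda v: v.entity_index)
    if strict and violations:
        raise ValidationError(violations)
    return entities, violations


# ---------------------------------------------------------------------------
# Entities -> JSON


def to_json(path: str | Path) -> dict[str, list[dict]]:
    """Read a PFB file back into per-node JSON objects (inverse of from_json).

    Enum symbols come back as their original values; relations are re-expanded
    into link fields. Only nodes that actually hold records appear in the map.
    """
    schema, metadata = read_metadata(path)
    d = dictionary_from_parts(schema, metadata)
    out: dict[str, list[dict]] = {name: [] for name in d.node_names}
    for e in read_entities(path):
        node = d.node(e.name)
        rec: dict[str, Any] = {}
        if e.id is not None:
            rec["id"] = e.id
        for p in node.properties:
            if p.name not in e.object:
                continue
            v = e.object[p.name]
            if v is None and not p.nullable:
                continue
            rec[p.name] = v
        grouped: dict[str, list[Relation]] = {}
        for r in e.relations:
            grouped.setdefault(r.dst_name, []).append(r)
        for dst, rels in grouped.items():
            link = node.link(dst)
            many = link is not None and link.multiplicity == Multiplicity.MANY_TO_MANY
            if many or len(rels) > 1:
                rec[dst] = [{"id": r.dst_id} for r in rels]
            else:
                rec[dst] = {"id": rels[0].dst_id}
        out[e.name].append(rec)
    return {name: recs for name, recs in out.items() if recs}


def make_blank_record(path: str | Path, node_name: str) -> dict:
    """Build a template record for one node of an existing PFB file.

    Every property key is present: nullable properties are null, strings and
    dates empty, numerics zero, booleans false, enums their first declared
    value. Link fields are present and empty.
    """
    schema, metadata = read_metadata(path)
    d = dictionary_from_parts(schema, metadata)
    node = d.node(node_name)
    if node is None:
        raise UnknownNodeError(f"no node named {node_name!r} in {path}")
    rec: dict[str, Any] = {"id": ""}
    for p in node.properties:
        if p.nullable:
            rec[p.name] = None
        elif p.type in ("string", "date"):
            rec[p.name] = ""
        elif p.type == "integer":
            rec[p.name] = 0
        elif p.type == "number":
            rec[p.name] = 0.0
        elif p.type == "boolean":
            rec[p.name] = False
        else:  # enum
            rec[p.name] = p.enum_values[0]
    for l in node.links:
        rec[l.dst] = [] if l.multiplicity == Multiplicity.MANY_TO_MANY else None
    return rec


# ---------------------------------------------------------------------------
# Validation


def _check_value(p, value) -> str | None:
    """Return the violated rule name for one (property, value) pair, or None."""
    if value is None:
        return None if p.nullable else "type"
    if p.type == "enum":
        if not isinstance(value, str):
            return "type"
        return None if value in p.enum_values else "enum"
    if p.type in ("string", "date"):
        return None if isinstance(value, str) else "type"
    if p.type == "integer":
        if isinstance(value, bool) or not isinstance(value, int):
            return "type"
        return None if LONG_MIN <= value <= LONG_MAX else "type"
    if p.type == "number":
        ok = not isinstance(value, bool) and isinstance(value, (int, float))
        return None if ok else "type"
    if p.type == "boolean":
        return None if isinstance(value, bool) else "type"
    return "type"  # pragma: no cover - dictionary loading guards types


def validate_records(
    d: DataDictionary, entities: Iterable[Entity]
) -> list[Violation]:
    """Check a batch of entities against the dictionary; violations are data.

    Per-record rules: unknown node/property, type and enum membership,
    missing required properties, link cardinality against the multiplicity
    class (only MANY_TO_MANY admits several relations to one destination).
    The single cross-record rule is ``dangling_relation``: a relation whose
    target (node, id) does not occur in the batch.
    """
    batch = list(entities)
    known_ids = {(e.name, e.id) for e in batch if e.id is not None}
    violations: list[Violation] = []

    for idx, e in enumerate(batch):
        node = d.node(e.name)
        if node is None:
            violations.append(
                Violation(idx, e.name, "", "unknown_node",
                          f"entity {idx} names unknown node {e.name!r}")
            )
            continue
        for key, value in e.object.items():
            p = node.property(key)
            if p is None:
                violations.append(
                    Violation(idx, e.name, key, "unknown_property",
                              f"{e.name} has no property {key!r}")
                )
                continue
            rule = _check_value(p, value)
            if rule == "type":
                violations.append(
                    Violation(idx, e.name, key, "type",
                              f"{e.name}.{key}: {value!r} is not a valid "
                              f"{p.type}")
                )
            elif rule == "enum":
                violations.append(
                    Violation(idx, e.name, key, "enum",
                              f"{e.name}.{key}: {value!r} not in "
                              f"{p.enum_values}")
                )
        for p in node.properties:
            if p.required and e.object.get(p.name) is None:
                violations.append(
                    Violation(idx, e.name, p.name, "required",
                              f"{e.name}.{p.name} is required")
                )

        counts = Counter(r.dst_name for r in e.relations)
        for r in e.relations:
            if not isinstance(r.dst_id, str):
                violations.append(
                    Violation(idx, e.name, r.dst_name, "type",
                              f"relation id {r.dst_id!r} is not a string")
                )
        for dst, n in counts.items():
            if d.node(dst) is None:
                violations.append(
                    Violation(idx, e.name, dst, "unknown_node",
                              f"relation targets unknown node {dst!r}")
                )
                continue
            link = node.link(dst)
            if link is None:
                violations.append(
                    Violation(idx, e.name, dst, "multiplicity",
                              f"{e.name} declares no link to {dst!r}")
                )
                continue
            if n > 1 and link.multiplicity != Multiplicity.MANY_TO_MANY:
                violations.append(
                    Violation(idx, e.name, dst, "multiplicity",
                              f"{n} relations to {dst!r} under "
                              f"{link.multiplicity.value}")
                )
        for l in node.links:
            if l.required and counts.get(l.dst, 0) == 0:
                violations.append(
                    Violation(idx, e.name, l.dst, "required",
                              f"link {e.name} -> {l.dst} is required")
                )
        for r in e.relations:
            if (
                isinstance(r.dst_id, str)
                and d.node(r.dst_name) is not None
                and (r.dst_name, r.dst_id) not in known_ids
            ):
                violations.append(
                    Violation(idx, e.name, r.dst_name, "dangling_relation",
                              f"no {r.dst_name} record with id {r.dst_id!r} "
                              "in this batch")
                )
    return violations


# ---------------------------------------------------------------------------
# Directory helpers (one <node>.json array, or <node>.ndjson, per node)


def read_json_dir(directory: str | Path) -> dict[str, list[dict]]:
    directory = Path(directory)
    out: dict[str, list[dict]] = {}
    for p in sorted(directory.glob("*.json")):
        with open(p) as fo:
            data = json.load(fo)
        out[p.stem] = data if isinstance(data, list) else [data]
    for p in sorted(directory.glob("*.ndjson")):
        with open(p) as fo:
            out[p.stem] = [json.loads(line) for line in fo if line.strip()]
    return out


def write_json_dir(
    records: dict[str, list[dict]], directory: str | Path, ndjson: bool = False
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for node, recs in records.items():
        if ndjson:
            with open(directory / f"{node}.ndjson", "w") as fo:
                for rec in recs:
                    fo.write(json.dumps(rec) + "\n")
        else:
            with open(directory / f"{node}.json", "w") as fo:
                json.dump(recs, fo, indent=2)
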