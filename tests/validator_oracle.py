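"""Brute-force, rule-by-rule record checker used as the validation oracle.

Each rule is its own full pass over the batch, written independently of
``pfb.convert.validate_records``. Findings are reported as hashable tuples
``(entity_index, node, property, rule)`` so suites can compare rule-by-rule
set equality.
"""

from __future__ import annotations

LONG_MIN, LONG_MAX = -(2**63), 2**63 - 1


def _node_def(d, name):
    for n in d.nodes:
        if n.name == name:
            return n
    return None


def check_unknown_node(d, batch):
    found = set()
    for i, e in enumerate(batch):
        if _node_def(d, e.name) is None:
            found.add((i, e.name, "", "unknown_node"))
            continue
        for dst in {r.dst_name for r in e.relations}:
            if _node_def(d, dst) is None:
                found.add((i, e.name, dst, "unknown_node"))
    return found


def check_unknown_property(d, batch):
    found = set()
    for i, e in enumerate(batch):
        nd = _node_def(d, e.name)
        if nd is None:
            continue
        declared = {p.name for p in nd.properties}
        for key in e.object:
            if key not in declared:
                found.add((i, e.name, key, "unknown_property"))
    return found


def _value_bad(p, v):
    if v is None:
        return not p.nullable
    if p.type in ("string", "date"):
        return not isinstance(v, str)
    if p.type == "enum":
        return not isinstance(v, str)
    if p.type == "integer":
        return isinstance(v, bool) or not isinstance(v, int) or not (
            LONG_MIN <= v <= LONG_MAX
        )
    if p.type == "number":
        return isinstance(v, bool) or not isinstance(v, (int, float))
    if p.type == "boolean":
        return not isinstance(v, bool)
    return True


def check_type(d, batch):
    found = set()
    for i, e in enumerate(batch):
        nd = _node_def(d, e.name)
        if nd is None:
            continue
        for key, v in e.object.items():
            for p in nd.properties:
                if p.name == key and _value_bad(p, v):
                    found.add((i, e.name, key, "type"))
        for r in e.relations:
            if not isinstance(r.dst_id, str):
                found.add((i, e.name, r.dst_name, "type"))
    return found


def check_enum(d, batch):
    found = set()
    for i, e in enumerate(batch):
        nd = _node_def(d, e.name)
        if nd is None:
            continue
        for p in nd.properties:
            if p.type != "enum":
                continue
            v = e.object.get(p.name)
            if isinstance(v, str) and v not in p.enum_values:
                found.add((i, e.name, p.name, "enum"))
    return found


def check_required(d, batch):
    found = set()
    for i, e in enumerate(batch):
        nd = _node_def(d, e.name)
        if nd is None:
            continue
        for p in nd.properties:
            if p.required and e.object.get(p.name) is None:
                found.add((i, e.name, p.name, "required"))
        for l in nd.links:
            if l.required and not any(r.dst_name == l.dst for r in e.relations):
                found.add((i, e.name, l.dst, "required"))
    return found


def check_multiplicity(d, batch):
    found = set()
    for i, e in enumerate(batch):
        nd = _node_def(d, e.name)
        if nd is None:
            continue
        per_dst: dict[str, int] = {}
        for r in e.relations:
            per_dst[r.dst_name] = per_dst.get(r.dst_name, 0) + 1
        for dst, n in per_dst.items():
            if _node_def(d, dst) is None:
                continue
            link = next((l for l in nd.links if l.dst == dst), None)
            if link is None:
                found.add((i, e.name, dst, "multiplicity"))
            elif n > 1 and link.multiplicity.value != "MANY_TO_MANY":
                found.add((i, e.name, dst, "multiplicity"))
    return found


def check_dangling(d, batch):
    ids = {(e.name, e.id) for e in batch if e.id is not None}
    found = set()
    for i, e in enumerate(batch):
        if _node_def(d, e.name) is None:
            continue
        for r in e.relations:
            if (
                isinstance(r.dst_id, str)
                and _node_def(d, r.dst_name) is not None
                and (r.dst_name, r.dst_id) not in ids
            ):
                found.add((i, e.name, r.dst_name, "dangling_relation"))
    return found


ALL_CHECKS = {
    "unknown_node": check_unknown_node,
    "unknown_property": check_unknown_property,
    "type": check_type,
    "enum": check_enum,
    "required": check_required,
    "multiplicity": check_multiplicity,
    "dangling_relation": check_dangling,
}


def brute_force_violations(d, batch) -> set[tuple]:
    batch = list(batch)
    out: set[tuple] = set()
    for check in ALL_CHECKS.values():
        out |= check(d, batch)
    return out
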