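"""Schema-level rewrites of existing PFB files.

All transforms are whole-file copy operations: the input is read, the
dictionary is edited, the schema recompiled, and every entity rewritten to
the output path. Record payload *values* are never touched — only names and
ontology references change — so entity counts and per-node value multisets
are invariant under every transform here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import NameCollisionError, UnknownNodeError, UnknownPropertyError
from .model import DataDictionary, Entity
from .pfb_io import DEFAULT_CODEC, read_entities, read_metadata, write_pfb
from .schema_compiler import build_metadata, compile_schema, dictionary_from_parts


@dataclass
class TransformSummary:
    """What a transform did: entities rewritten, reference rewrites per node."""

    entities_written: int = 0
    entities_changed: int = 0
    references_rewritten: dict[str, int] = field(default_factory=dict)

    @property
    def total_references(self) -> int:
        return sum(self.references_rewritten.values())


def _is_identifier(s: str) -> bool:
    return bool(s) and (s[0].isalpha() or s[0] == "_") and all(
        c.isalnum() or c == "_" for c in s
    )


def _load(path: str | Path) -> tuple[DataDictionary, list[Entity], str]:
    schema, metadata = read_metadata(path)
    d = dictionary_from_parts(schema, metadata)
    # re-detect the input codec so the copy keeps it
    from . import avro

    with open(path, "rb") as fo:
        codec = avro.ContainerReader(fo).codec
    return d, list(read_entities(path)), codec


def _write(path: str | Path, d: DataDictionary, entities: list[Entity], codec: str) -> int:
    schema = compile_schema(d)
    return write_pfb(path, schema, build_metadata(d), entities, codec=codec or DEFAULT_CODEC)


def rename_node(
    in_path: str | Path, out_path: str | Path, old: str, new: str
) -> TransformSummary:
    """Rename a node type everywhere: schema branch, metadata, entity names,
    and every relation pointing at it."""
    d, entities, codec = _load(in_path)
    if d.node(old) is None:
        raise UnknownNodeError(f"no node named {old!r}")
    if not _is_identifier(new):
        raise NameCollisionError(f"{new!r} is not a legal node identifier")
    if d.node(new) is not None:
        raise NameCollisionError(f"a node named {new!r} already exists")

    for n in d.nodes:
        if n.name == old:
            n.name = new
        for l in n.links:
            if l.dst == old:
                l.dst = new

    summary = TransformSummary()
    for e in entities:
        changed = False
        if e.name == old:
            e.name = new
            changed = True
        for r in e.relations:
            if r.dst_name == old:
                r.dst_name = new
                changed = True
        if changed:
            summary.entities_changed += 1
    summary.entities_written = _write(out_path, d, entities, codec)
    return summary


def rename_property(
    in_path: str | Path, out_path: str | Path, node: str, old: str, new: str
) -> TransformSummary:
    """Rename one property of one node: schema field, metadata entry, and
    every entity's payload key."""
    d, entities, codec = _load(in_path)
    nd = d.node(node)
    if nd is None:
        raise UnknownNodeError(f"no node named {node!r}")
    if nd.property(old) is None:
        raise UnknownPropertyError(f"{node} has no property {old!r}")
    if not _is_identifier(new):
        raise NameCollisionError(f"{new!r} is not a legal property identifier")
    if nd.property(new) is not None or nd.link(new) is not None:
        raise NameCollisionError(f"{node} already has a field named {new!r}")

    for p in nd.properties:
        if p.name == old:
            p.name = new

    summary = TransformSummary()
    for e in entities:
        if e.name == node and old in e.object:
            # rebuild to keep key order stable
            e.object = {new if k == old else k: v for k, v in e.object.items()}
            summary.entities_changed += 1
    summary.entities_written = _write(out_path, d, entities, codec)
    return summary


def rewrite_reference(ref: str, mapping: dict[str, str]) -> tuple[str, bool]:
    """Longest-prefix substitution of one ontology reference URI."""
    best = ""
    for prefix in mapping:
        if prefix and ref.startswith(prefix) and len(prefix) > len(best):
            best = prefix
    if not best:
        return ref, False
    return mapping[best] + ref[len(best):], True


def retarget_ontology(
    in_path: str | Path, out_path: str | Path, mapping: dict[str, str]
) -> TransformSummary:
    """Swap ontology vocabularies by URI prefix (e.g. CDISC -> NCIt).

    Rewrites every node- and property-level ontology_reference, plus any
    annotation value stored under the key ``"ontology_reference"``, using
    longest-prefix substitution. Data records are untouched; the summary
    counts rewrites per node.
    """
    d, entities, codec = _load(in_path)
    summary = TransformSummary()

    def count(node_name: str, n: int = 1) -> None:
        summary.references_rewritten[node_name] = (
            summary.references_rewritten.get(node_name, 0) + n
        )

    for n in d.nodes:
        new_ref, hit = rewrite_reference(n.ontology_reference, mapping)
        if hit:
            n.ontology_reference = new_ref
            count(n.name)
        if "ontology_reference" in n.values:
            new_ref, hit = rewrite_reference(n.values["ontology_reference"], mapping)
            if hit:
                n.values["ontology_reference"] = new_ref
                count(n.name)
        for p in n.properties:
            new_ref, hit = rewrite_reference(p.ontology_reference, mapping)
            if hit:
                p.ontology_reference = new_ref
                count(n.name)
            if "ontology_reference" in p.values:
                new_ref, hit = rewrite_reference(
                    p.values["ontology_reference"], mapping
                )
                if hit:
                    p.values["ontology_reference"] = new_ref
                    count(n.name)

    summary.entities_written = _write(out_path, d, entities, codec)
    return summary
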