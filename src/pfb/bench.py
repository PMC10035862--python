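"""Desk-scale size and throughput experiments.

Reproduces the *shape* of the format comparison — serialized size of the same
simulated batch as plain JSON, bzip2-compressed JSON, uncompressed PFB and
deflate-compressed PFB, plus read/write throughput. Absolute numbers depend
on the simulator's payloads and the local hardware; the stable, meaningful
result is the ordering (PFB < JSON, compressed < uncompressed).
"""

from __future__ import annotations

import bz2
import json
import statistics
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path

from .convert import from_json
from .model import DataDictionary
from .pfb_io import read_entities, write_pfb
from .schema_compiler import build_metadata, compile_schema
from .simulator import SimConfig, simulate_records


@dataclass
class SizeRow:
    format: str
    bytes: int


@dataclass
class ThroughputRow:
    format: str
    read_records_per_s: float
    write_records_per_s: float
    read_reps: list[float] = field(default_factory=list)
    write_reps: list[float] = field(default_factory=list)


def _json_bytes(records: dict[str, list[dict]]) -> bytes:
    # concatenated per-node arrays, as a directory of <node>.json would hold
    return b"".join(json.dumps(recs).encode() for recs in records.values())


def size_report(
    d: DataDictionary, records_per_node: int, seed: int
) -> list[SizeRow]:
    """Serialize one simulated batch four ways and report byte sizes."""
    cfg = SimConfig(
        n_nodes=len(d.nodes),
        total_attributes=sum(len(n.properties) for n in d.nodes),
        records_per_node=records_per_node,
        seed=seed,
    )
    records = simulate_records(d, cfg)
    entities, _ = from_json(d, records)
    schema = compile_schema(d)
    metadata = build_metadata(d)
    raw_json = _json_bytes(records)
    rows = [
        SizeRow("JSON", len(raw_json)),
        SizeRow("JSON-compressed", len(bz2.compress(raw_json))),
    ]
    with tempfile.TemporaryDirectory() as tmp:
        for label, codec in (("PFB", "null"), ("PFB-compressed", "deflate")):
            path = Path(tmp) / f"{codec}.pfb"
            write_pfb(path, schema, metadata, entities, codec=codec)
            rows.append(SizeRow(label, path.stat().st_size))
    return rows


def throughput_report(
    d: DataDictionary, records_per_node: int, seed: int, reps: int = 3
) -> list[ThroughputRow]:
    """Time full write and read passes for PFB and JSON; median of ``reps``.

    Purely informational — rates depend on the machine at hand.
    """
    cfg = SimConfig(
        n_nodes=len(d.nodes),
        total_attributes=sum(len(n.properties) for n in d.nodes),
        records_per_node=records_per_node,
        seed=seed,
    )
    records = simulate_records(d, cfg)
    entities, _ = from_json(d, records)
    n = max(len(entities), 1)
    schema = compile_schema(d)
    metadata = build_metadata(d)

    rows = []
    with tempfile.TemporaryDirectory() as tmp:
        pfb_path = Path(tmp) / "bench.pfb"
        json_dir = Path(tmp) / "json"
        json_dir.mkdir()

        pfb_write, pfb_read = [], []
        for _ in range(reps):
            t0 = time.perf_counter()
            write_pfb(pfb_path, schema, metadata, entities, codec="deflate")
            pfb_write.append(n / (time.perf_counter() - t0))
            t0 = time.perf_counter()
            for _e in read_entities(pfb_path):
                pass
            pfb_read.append(n / (time.perf_counter() - t0))
        rows.append(
            ThroughputRow("PFB", statistics.median(pfb_read),
                          statistics.median(pfb_write), pfb_read, pfb_write)
        )

        json_write, json_read = [], []
        for _ in range(reps):
            t0 = time.perf_counter()
            for node, recs in records.items():
                (json_dir / f"{node}.json").write_text(json.dumps(recs))
            json_write.append(n / (time.perf_counter() - t0))
            t0 = time.perf_counter()
            for node in records:
                json.loads((json_dir / f"{node}.json").read_text())
            json_read.append(n / (time.perf_counter() - t0))
        rows.append(
            ThroughputRow("JSON", statistics.median(json_read),
                          statistics.median(json_write), json_read, json_write)
        )
    return rows
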