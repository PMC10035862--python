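"""Apache Avro binary encoding and object container files.

This module implements the subset of Avro 1.11 that PFB relies on: JSON schema
parsing, the binary datum encoding, object container files (OCF) with the
``null`` and ``deflate`` codecs, and the Parsing Canonical Form used to compare
schemas across implementations. Files produced here follow the published
container layout (``Obj\\x01`` magic, metadata map with ``avro.schema`` and
``avro.codec``, 16-byte sync markers between blocks) and are readable by any
conforming Avro reader.

Only writer-schema decoding is provided; schema resolution between different
reader/writer schemas (schema evolution) is out of scope.
"""

from __future__ import annotations

import io
import json
import os
import struct
import zlib
from typing import Any, BinaryIO, Iterable, Iterator

from .errors import CorruptFileError, SchemaError

MAGIC = b"Obj\x01"
SYNC_SIZE = 16
CODECS = ("null", "deflate")

PRIMITIVES = frozenset(
    {"null", "boolean", "int", "long", "float", "double", "bytes", "string"}
)

LONG_MIN = -(1 << 63)
LONG_MAX = (1 << 63) - 1


class Branch:
    """Explicit union-branch selection for encoding.

    Wrap a datum as ``Branch("NodeName", value)`` to force the union branch
    with that (full)name instead of relying on positional type matching.
    """

    __slots__ = ("name", "value")

    def __init__(self, name: str, value: Any):
        self.name = name
        self.value = value


# ---------------------------------------------------------------------------
# Schema parsing


def _fullname(name: str, namespace: str | None) -> str:
    if "." in name or not namespace:
        return name
    return f"{namespace}.{name}"


def _is_identifier(s: str) -> bool:
    if not s:
        return False
    if not (s[0].isalpha() or s[0] == "_"):
        return False
    return all(c.isalnum() or c == "_" for c in s)


def _parse(obj: Any, names: dict[str, dict], namespace: str | None) -> Any:
    """Parse one schema node; named types are registered in ``names``.

    Returns either a primitive type name (str) or a dict with a ``type`` key
    in {record, enum, array, map, fixed, union}.
    """
    if isinstance(obj, str):
        if obj in PRIMITIVES:
            return obj
        full = _fullname(obj, namespace)
        if full in names:
            return names[full]
        if obj in names:
            return names[obj]
        raise SchemaError(f"unknown type name {obj!r}")
    if isinstance(obj, list):
        branches = [_parse(b, names, namespace) for b in obj]
        if any(isinstance(b, dict) and b["type"] == "union" for b in branches):
            raise SchemaError("unions may not immediately contain unions")
        return {"type": "union", "branches": branches}
    if not isinstance(obj, dict):
        raise SchemaError(f"invalid schema node: {obj!r}")

    t = obj.get("type")
    if isinstance(t, (dict, list)):
        return _parse(t, names, namespace)
    if t in PRIMITIVES:
        return t
    if t == "array":
        return {"type": "array", "items": _parse(obj["items"], names, namespace)}
    if t == "map":
        return {"type": "map", "values": _parse(obj["values"], names, namespace)}
    if t in ("record", "enum", "fixed", "error"):
        name = obj.get("name")
        if not name or not all(_is_identifier(p) for p in name.split(".")):
            raise SchemaError(f"invalid name {name!r} for {t}")
        ns = obj.get("namespace", namespace) if "." not in name else None
        full = _fullname(name, ns)
        if full in names:
            raise SchemaError(f"duplicate type name {full!r}")
        node: dict[str, Any] = {"type": "record" if t == "error" else t, "name": full}
        names[full] = node
        if t == "enum":
            symbols = obj.get("symbols")
            if (
                not isinstance(symbols, list)
                or not symbols
                or len(set(symbols)) != len(symbols)
                or not all(_is_identifier(s) for s in symbols)
            ):
                raise SchemaError(f"invalid symbols for enum {full!r}")
            node["symbols"] = list(symbols)
        elif t == "fixed":
            size = obj.get("size")
            if not isinstance(size, int) or size < 0:
                raise SchemaError(f"invalid size for fixed {full!r}")
            node["size"] = size
        else:
            fields = obj.get("fields")
            if not isinstance(fields, list):
                raise SchemaError(f"record {full!r} has no fields array")
            parsed_fields = []
            seen = set()
            for f in fields:
                fname = f.get("name")
                if not _is_identifier(fname or ""):
                    raise SchemaError(f"invalid field name {fname!r} in {full!r}")
                if fname in seen:
                    raise SchemaError(f"duplicate field {fname!r} in {full!r}")
                seen.add(fname)
                pf = {"name": fname, "type": _parse(f["type"], names, ns)}
                if "default" in f:
                    pf["default"] = f["default"]
                parsed_fields.append(pf)
            node["fields"] = parsed_fields
        return node
    raise SchemaError(f"unsupported type: {t!r}")


class Schema:
    """A parsed Avro schema: raw JSON plus a resolved type tree."""

    def __init__(self, source: str | dict | list):
        if isinstance(source, str):
            try:
                source = json.loads(source)
            except json.JSONDecodeError as e:
                raise SchemaError(f"schema is not valid JSON: {e}") from e
        self.json = source
        self.names: dict[str, dict] = {}
        self.root = _parse(source, self.names, None)

    def canonical_form(self) -> str:
        return canonical_form(self.json)


# ---------------------------------------------------------------------------
# Binary encoding


def _encode_long(n: int, out: bytearray) -> None:
    if not isinstance(n, int) or isinstance(n, bool):
        raise SchemaError(f"expected int, got {type(n).__name__}")
    if not (LONG_MIN <= n <= LONG_MAX):
        raise SchemaError(f"long out of 64-bit range: {n}")
    u = (n << 1) ^ (n >> 63)  # zigzag on 64-bit two's complement
    u &= (1 << 64) - 1
    while True:
        b = u & 0x7F
        u >>= 7
        if u:
            out.append(b | 0x80)
        else:
            out.append(b)
            break


def _encode_bytes(b: bytes, out: bytearray) -> None:
    _encode_long(len(b), out)
    out += b


def encode_datum(datum: Any, node: Any, out: bytearray) -> None:
    kind = node if isinstance(node, str) else node["type"]
    if kind == "null":
        if datum is not None:
            raise SchemaError(f"expected null, got {datum!r}")
    elif kind == "boolean":
        if not isinstance(datum, bool):
            raise SchemaError(f"expected bool, got {datum!r}")
        out.append(1 if datum else 0)
    elif kind in ("int", "long"):
        _encode_long(datum, out)
    elif kind in ("float", "double"):
        if isinstance(datum, bool) or not isinstance(datum, (int, float)):
            raise SchemaError(f"expected number, got {datum!r}")
        out += struct.pack("<f" if kind == "float" else "<d", float(datum))
    elif kind == "bytes":
        if not isinstance(datum, bytes):
            raise SchemaError(f"expected bytes, got {datum!r}")
        _encode_bytes(datum, out)
    elif kind == "string":
        if not isinstance(datum, str):
            raise SchemaError(f"expected str, got {datum!r}")
        _encode_bytes(datum.encode("utf-8"), out)
    elif kind == "enum":
        try:
            idx = node["symbols"].index(datum)
        except (ValueError, TypeError):
            raise SchemaError(
                f"{datum!r} is not a symbol of enum {node['name']}"
            ) from None
        _encode_long(idx, out)
    elif kind == "array":
        if not isinstance(datum, (list, tuple)):
            raise SchemaError(f"expected list, got {datum!r}")
        if datum:
            _encode_long(len(datum), out)
            for item in datum:
                encode_datum(item, node["items"], out)
        _encode_long(0, out)
    elif kind == "map":
        if not isinstance(datum, dict):
            raise SchemaError(f"expected dict, got {datum!r}")
        if datum:
            _encode_long(len(datum), out)
            for k, v in datum.items():
                _encode_bytes(k.encode("utf-8"), out)
                encode_datum(v, node["values"], out)
        _encode_long(0, out)
    elif kind == "fixed":
        if not isinstance(datum, bytes) or len(datum) != node["size"]:
            raise SchemaError(f"expected {node['size']} bytes for fixed")
        out += datum
    elif kind == "record":
        if not isinstance(datum, dict):
            raise SchemaError(f"expected dict for record {node['name']}, got {datum!r}")
        for f in node["fields"]:
            if f["name"] in datum:
                value = datum[f["name"]]
            elif "default" in f:
                value = f["default"]
            else:
                raise SchemaError(
                    f"missing field {f['name']!r} of record {node['name']}"
                )
            encode_datum(value, f["type"], out)
    elif kind == "union":
        idx, value = _select_branch(datum, node["branches"])
        _encode_long(idx, out)
        encode_datum(value, node["branches"][idx], out)
    else:  # pragma: no cover - parse guards against this
        raise SchemaError(f"unsupported kind {kind!r}")


def _select_branch(datum: Any, branches: list) -> tuple[int, Any]:
    if isinstance(datum, Branch):
        for i, b in enumerate(branches):
            if isinstance(b, dict) and b.get("name", "").split(".")[-1] == datum.name:
                return i, datum.value
        raise SchemaError(f"no union branch named {datum.name!r}")
    for i, b in enumerate(branches):
        if _branch_matches(datum, b):
            return i, datum
    raise SchemaError(f"no union branch accepts {datum!r}")


def _branch_matches(datum: Any, node: Any) -> bool:
    kind = node if isinstance(node, str) else node["type"]
    if kind == "null":
        return datum is None
    if kind == "boolean":
        return isinstance(datum, bool)
    if kind in ("int", "long"):
        return isinstance(datum, int) and not isinstance(datum, bool)
    if kind in ("float", "double"):
        return isinstance(datum, (int, float)) and not isinstance(datum, bool)
    if kind == "string":
        return isinstance(datum, str)
    if kind in ("bytes", "fixed"):
        return isinstance(datum, bytes)
    if kind == "enum":
        return isinstance(datum, str) and datum in node["symbols"]
    if kind == "array":
        return isinstance(datum, (list, tuple))
    if kind in ("map", "record"):
        return isinstance(datum, dict)
    return False


# ---------------------------------------------------------------------------
# Binary decoding


class _Reader:
    def __init__(self, fo: BinaryIO):
        self._fo = fo
        self._pushback = b""

    def push(self, b: bytes) -> None:
        self._pushback = b + self._pushback

    def read(self, n: int) -> bytes:
        if self._pushback:
            take, self._pushback = self._pushback[:n], self._pushback[n:]
            rest = self._fo.read(n - len(take))
            b = take + rest
        else:
            b = self._fo.read(n)
        if len(b) != n:
            raise CorruptFileError("unexpected end of file")
        return b

    def read_long(self) -> int:
        u = shift = 0
        while True:
            b = self.read(1)[0]
            u |= (b & 0x7F) << shift
            if not (b & 0x80):
                break
            shift += 7
            if shift > 70:
                raise CorruptFileError("malformed varint")
        return (u >> 1) ^ -(u & 1)

    def read_bytes(self) -> bytes:
        n = self.read_long()
        if n < 0:
            raise CorruptFileError("negative byte-length")
        return self.read(n)


def decode_datum(r: _Reader, node: Any) -> Any:
    kind = node if isinstance(node, str) else node["type"]
    if kind == "null":
        return None
    if kind == "boolean":
        return r.read(1) != b"\x00"
    if kind in ("int", "long"):
        return r.read_long()
    if kind == "float":
        return struct.unpack("<f", r.read(4))[0]
    if kind == "double":
        return struct.unpack("<d", r.read(8))[0]
    if kind == "bytes":
        return r.read_bytes()
    if kind == "string":
        return r.read_bytes().decode("utf-8")
    if kind == "enum":
        idx = r.read_long()
        symbols = node["symbols"]
        if not (0 <= idx < len(symbols)):
            raise CorruptFileError(f"enum index {idx} out of range")
        return symbols[idx]
    if kind == "fixed":
        return r.read(node["size"])
    if kind == "array":
        items: list = []
        while True:
            n = r.read_long()
            if n == 0:
                return items
            if n < 0:
                n = -n
                r.read_long()  # byte size of block, unused
            for _ in range(n):
                items.append(decode_datum(r, node["items"]))
    if kind == "map":
        result: dict = {}
        while True:
            n = r.read_long()
            if n == 0:
                return result
            if n < 0:
                n = -n
                r.read_long()
            for _ in range(n):
                key = r.read_bytes().decode("utf-8")
                result[key] = decode_datum(r, node["values"])
    if kind == "record":
        return {f["name"]: decode_datum(r, f["type"]) for f in node["fields"]}
    if kind == "union":
        idx = r.read_long()
        branches = node["branches"]
        if not (0 <= idx < len(branches)):
            raise CorruptFileError(f"union index {idx} out of range")
        return decode_datum(r, branches[idx])
    raise SchemaError(f"unsupported kind {kind!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# Object container files

_META_SCHEMA = {"type": "map", "values": "bytes"}


class ContainerWriter:
    """Streaming writer for an Avro object container file."""

    def __init__(
        self,
        fo: BinaryIO,
        schema: Schema,
        codec: str = "deflate",
        block_records: int = 1000,
        extra_meta: dict[str, bytes] | None = None,
    ):
        if codec not in CODECS:
            raise SchemaError(f"unsupported codec {codec!r} (use one of {CODECS})")
        self._fo = fo
        self._schema = schema
        self._codec = codec
        self._block_records = block_records
        self._buffer = bytearray()
        self._buffered = 0
        self.count = 0
        self._sync = os.urandom(SYNC_SIZE)
        meta = {
            "avro.schema": json.dumps(schema.json, separators=(",", ":")).encode(),
            "avro.codec": codec.encode(),
        }
        if extra_meta:
            meta.update(extra_meta)
        header = bytearray()
        header += MAGIC
        encode_datum(meta, _parse(_META_SCHEMA, {}, None), header)
        header += self._sync
        fo.write(bytes(header))

    def append(self, datum: Any) -> None:
        tmp = bytearray()
        encode_datum(datum, self._schema.root, tmp)  # encode apart: keep block intact on error
        self._buffer += tmp
        self._buffered += 1
        self.count += 1
        if self._buffered >= self._block_records:
            self._flush_block()

    def _flush_block(self) -> None:
        if not self._buffered:
            return
        data = bytes(self._buffer)
        if self._codec == "deflate":
            comp = zlib.compressobj(6, zlib.DEFLATED, -15)
            data = comp.compress(data) + comp.flush()
        out = bytearray()
        _encode_long(self._buffered, out)
        _encode_long(len(data), out)
        out += data
        out += self._sync
        self._fo.write(bytes(out))
        self._buffer.clear()
        self._buffered = 0

    def close(self) -> None:
        self._flush_block()


class ContainerReader:
    """Iterates the records of an Avro object container file."""

    def __init__(self, fo: BinaryIO):
        self._fo = fo
        r = _Reader(fo)
        magic = fo.read(4)
        if len(magic) < 4 or magic != MAGIC:
            raise CorruptFileError("not an Avro object container file (bad magic)")
        meta = decode_datum(r, _parse(_META_SCHEMA, {}, None))
        try:
            self.schema_json = json.loads(meta["avro.schema"].decode("utf-8"))
        except (KeyError, ValueError, UnicodeDecodeError) as e:
            raise CorruptFileError(f"invalid container schema header: {e}") from e
        self.codec = meta.get("avro.codec", b"null").decode("utf-8")
        if self.codec not in CODECS:
            raise CorruptFileError(f"unsupported codec {self.codec!r}")
        self.meta = meta
        self.schema = Schema(self.schema_json)
        self._sync = r.read(SYNC_SIZE)
        self._r = r

    def __iter__(self) -> Iterator[Any]:
        while True:
            probe = self._fo.read(1)
            if not probe:
                return
            self._r.push(probe)
            n = self._r.read_long()
            size = self._r.read_long()
            if n < 0 or size < 0:
                raise CorruptFileError("negative block framing")
            data = self._r.read(size)
            sync = self._r.read(SYNC_SIZE)
            if sync != self._sync:
                raise CorruptFileError("sync marker mismatch")
            if self.codec == "deflate":
                try:
                    data = zlib.decompressobj(-15).decompress(data)
                except zlib.error as e:
                    raise CorruptFileError(f"deflate block corrupt: {e}") from e
            block = _Reader(io.BytesIO(data))
            for _ in range(n):
                yield decode_datum(block, self.schema.root)


def write_container(
    path: str,
    schema: Schema | dict | list | str,
    records: Iterable[Any],
    codec: str = "deflate",
    extra_meta: dict[str, bytes] | None = None,
) -> int:
    if not isinstance(schema, Schema):
        schema = Schema(schema)
    with open(path, "wb") as fo:
        w = ContainerWriter(fo, schema, codec=codec, extra_meta=extra_meta)
        for rec in records:
            w.append(rec)
        w.close()
        return w.count


def read_container(path: str) -> Iterator[Any]:
    with open(path, "rb") as fo:
        yield from ContainerReader(fo)


# ---------------------------------------------------------------------------
# Parsing Canonical Form

_PCF_FIELD_ORDER = ("name", "type", "fields", "symbols", "items", "values", "size")


def canonical_form(schema: dict | list | str) -> str:
    """Return the Avro Parsing Canonical Form of a schema as a JSON string.

    Strips everything but {name, type, fields, symbols, items, values, size},
    resolves names to fullnames, orders keys canonically and emits minimal
    JSON, so two schemas are semantically equal for parsing iff their
    canonical forms are byte-identical.
    """
    return json.dumps(
        _pcf(schema, None), separators=(",", ":"), ensure_ascii=False
    )


def _pcf(obj: Any, namespace: str | None) -> Any:
    if isinstance(obj, str):
        return obj if obj in PRIMITIVES else _fullname(obj, namespace)
    if isinstance(obj, list):
        return [_pcf(b, namespace) for b in obj]
    t = obj.get("type")
    if isinstance(t, (dict, list)):
        return _pcf(t, namespace)
    if t in PRIMITIVES:
        return t
    if t == "array":
        return {"type": "array", "items": _pcf(obj["items"], namespace)}
    if t == "map":
        return {"type": "map", "values": _pcf(obj["values"], namespace)}
    name = obj["name"]
    ns = obj.get("namespace", namespace) if "." not in name else None
    full = _fullname(name, ns)
    out: dict[str, Any] = {"name": full, "type": t}
    if t == "record":
        out["fields"] = [
            {"name": f["name"], "type": _pcf(f["type"], ns)} for f in obj["fields"]
        ]
    elif t == "enum":
        out["symbols"] = list(obj["symbols"])
    elif t == "fixed":
        out["size"] = obj["size"]
    ordered = {k: out[k] for k in _PCF_FIELD_ORDER if k in out}
    return ordered
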