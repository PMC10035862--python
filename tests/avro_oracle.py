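"""Independent Avro object-container reader used as a test oracle.

Written directly from the published Avro 1.11 specification (container
layout, binary encoding, Parsing Canonical Form) and deliberately kept
separate from — and structured differently to — the package's own codec:
it decodes straight off the raw JSON schema document with a lazily built
name environment, and shares no code with ``pfb.avro``.
"""

from __future__ import annotations

import json
import struct
import zlib

PRIMITIVE = {"null", "boolean", "int", "long", "float", "double", "bytes", "string"}


class OracleError(Exception):
    pass


class _Decoder:
    def __init__(self, buf: bytes):
        self.buf = buf
        self.pos = 0

    def take(self, n: int) -> bytes:
        if self.pos + n > len(self.buf):
            raise OracleError("truncated input")
        b = self.buf[self.pos : self.pos + n]
        self.pos += n
        return b

    def varlong(self) -> int:
        shift = acc = 0
        while True:
            byte = self.take(1)[0]
            acc |= (byte & 0x7F) << shift
            if not byte & 0x80:
                break
            shift += 7
        return (acc >> 1) ^ -(acc & 1)

    def at_end(self) -> bool:
        return self.pos >= len(self.buf)


def _resolve(schema, env, ns):
    if isinstance(schema, str) and schema not in PRIMITIVE:
        for candidate in (schema, f"{ns}.{schema}" if ns else schema):
            if candidate in env:
                return env[candidate], ns
        raise OracleError(f"unresolved type name {schema!r}")
    return schema, ns


def _register(schema, env, ns):
    name = schema["name"]
    space = schema.get("namespace", ns) if "." not in name else None
    full = name if "." in name or not space else f"{space}.{name}"
    env[full] = dict(schema, name=full)
    if "namespace" in env[full]:
        del env[full]["namespace"]
    return env[full], space


def _read(dec: _Decoder, schema, env, ns):
    schema, ns = _resolve(schema, env, ns)
    if isinstance(schema, list):  # union
        return _read(dec, schema[dec.varlong()], env, ns)
    t = schema if isinstance(schema, str) else schema["type"]
    if isinstance(t, (list, dict)):
        return _read(dec, t, env, ns)
    if t == "null":
        return None
    if t == "boolean":
        return dec.take(1) != b"\x00"
    if t in ("int", "long"):
        return dec.varlong()
    if t == "float":
        return struct.unpack("<f", dec.take(4))[0]
    if t == "double":
        return struct.unpack("<d", dec.take(8))[0]
    if t == "bytes":
        return dec.take(dec.varlong())
    if t == "string":
        return dec.take(dec.varlong()).decode("utf-8")
    if t == "fixed":
        _register(schema, env, ns)
        return dec.take(schema["size"])
    if t == "enum":
        reg, _ = _register(schema, env, ns)
        return reg["symbols"][dec.varlong()]
    if t == "array":
        out = []
        while True:
            n = dec.varlong()
            if n == 0:
                return out
            if n < 0:
                n, _ = -n, dec.varlong()
            out.extend(_read(dec, schema["items"], env, ns) for _ in range(n))
    if t == "map":
        out = {}
        while True:
            n = dec.varlong()
            if n == 0:
                return out
            if n < 0:
                n, _ = -n, dec.varlong()
            for _ in range(n):
                key = dec.take(dec.varlong()).decode("utf-8")
                out[key] = _read(dec, schema["values"], env, ns)
    if t == "record":
        reg, space = _register(schema, env, ns)
        return {
            f["name"]: _read(dec, f["type"], env, space) for f in schema["fields"]
        }
    raise OracleError(f"unsupported type {t!r}")


def read_container(path) -> tuple[dict, str, list]:
    """Decode a whole container file: (schema, codec, records)."""
    with open(path, "rb") as fo:
        dec = _Decoder(fo.read())
    if dec.take(4) != b"Obj\x01":
        raise OracleError("bad magic")
    meta = {}
    while True:
        n = dec.varlong()
        if n == 0:
            break
        if n < 0:
            n, _ = -n, dec.varlong()
        for _ in range(n):
            key = dec.take(dec.varlong()).decode("utf-8")
            meta[key] = dec.take(dec.varlong())
    sync = dec.take(16)
    schema = json.loads(meta["avro.schema"])
    codec = meta.get("avro.codec", b"null").decode()
    records = []
    while not dec.at_end():
        count = dec.varlong()
        nbytes = dec.varlong()
        payload = dec.take(nbytes)
        if dec.take(16) != sync:
            raise OracleError("sync mismatch")
        if codec == "deflate":
            payload = zlib.decompress(payload, wbits=-15)
        elif codec != "null":
            raise OracleError(f"codec {codec!r}")
        block = _Decoder(payload)
        for _ in range(count):
            records.append(_read(block, schema, {}, None))
        if not block.at_end():
            raise OracleError("trailing bytes in block")
    return schema, codec, records


# -- Parsing Canonical Form -------------------------------------------------

_KEEP = ("name", "type", "fields", "symbols", "items", "values", "size")


def canonical(schema) -> str:
    def norm(s, ns):
        if isinstance(s, str):
            if s in PRIMITIVE:
                return s
            return s if "." in s or not ns else f"{ns}.{s}"
        if isinstance(s, list):
            return [norm(x, ns) for x in s]
        t = s["type"]
        if isinstance(t, (dict, list)):
            return norm(t, ns)
        if t in PRIMITIVE:
            return t
        if t == "array":
            return {"type": "array", "items": norm(s["items"], ns)}
        if t == "map":
            return {"type": "map", "values": norm(s["values"], ns)}
        name = s["name"]
        space = s.get("namespace", ns) if "." not in name else None
        full = name if "." in name or not space else f"{space}.{name}"
        out = {"name": full, "type": t}
        if t == "record":
            out["fields"] = [
                {"name": f["name"], "type": norm(f["type"], space)}
                for f in s["fields"]
            ]
        elif t == "enum":
            out["symbols"] = s["symbols"]
        else:
            out["size"] = s["size"]
        return {k: out[k] for k in _KEEP if k in out}

    return json.dumps(norm(schema, None), separators=(",", ":"), ensure_ascii=False)
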