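# Methods

## The data model

A PFB file serializes a *graph data dictionary* plus its records. The
dictionary is a set of node types; each node carries

* typed properties — `string`, `integer`, `number`, `boolean`, `date`,
  `enum` (with a closed value list), each optionally `required` or
  `nullable` (mutually exclusive: required implies non-null), and each with
  an `ontology_reference` URI plus a free-form string map of annotations
  (ontology name, version, …);
* links to parent nodes, each with a cardinality class
  (`ONE_TO_ONE | ONE_TO_MANY | MANY_TO_ONE | MANY_TO_MANY`) and an optional
  `required` flag.

The link graph must be acyclic. Acyclicity is enforced at load time because
topological (parent-before-child) emission — which bulk importers need — is
only defined on a DAG; cycle detection and the declaration-order-stable
topological sort are delegated to `networkx`.

Records are wrapped in `Entity { id?, name, object, relations }`, where
`object` is a tagged union over one Avro record type per node (plus the
`Metadata` record) rather than a generic string map. The union preserves
per-node static typing: a reader can decode any entity without consulting
anything outside the file.

## Schema compilation choices

* **Metadata-first.** The `Metadata` entity is always the first record. The
  alternative — burying it anywhere in the stream — would force readers to
  scan the whole file before they know the ontology bindings. Readers treat
  this as a checked contract, not an assumption: a file whose first record
  is not `Metadata`, or which contains a second one, is rejected
  (`NotPFBError`).
* **Self-description is complete.** The in-file `Metadata` node entries
  include the link definitions (destination, multiplicity, required flag),
  and each Avro field carries `pfb_required` / `pfb_nullable` attributes
  (ignored by generic Avro readers); `date` properties are annotated strings
  (`pfb_format: date`) rather than numeric logical dates, for round-trip
  fidelity with heterogeneous upstream date strings. Together these make
  `compile_schema ∘ build_metadata` invertible: the full dictionary is
  reconstructed from a file with `dictionary_from_parts`.
* **Optionality on the wire.** Avro always writes every record field, so a
  non-required property must be null-wrapped to make *absence* encodable.
  `map_property_type` wraps only `nullable` properties (the declared value
  may be null); the compiler additionally wraps every non-required field.
  Consequently absence and explicit null coincide on the wire; the JSON
  converters disambiguate by declaration: a null in a nullable property is
  rendered as an explicit `null`, a null in an optional non-nullable
  property is rendered as an absent key. Canonical JSON input (what the
  simulator emits, and what `to_json` produces) therefore round-trips
  byte-for-byte; input that writes `null` into an optional non-nullable key
  is normalized to absence.
* **Enum escaping.** Avro enum symbols must match `[A-Za-z_][A-Za-z0-9_]*`,
  but clinical value sets contain strings like `"Not Reported"` or
  `"Stage I"`. Every character outside `[A-Za-z0-9]` (and a leading digit)
  is escaped as `_x<hex>_`. Because a literal underscore is itself escaped,
  every underscore in a symbol delimits an escape — the map is injective
  over all strings, needs no stored lookup table, and collisions are
  impossible by construction (property-tested rather than handled with
  suffixes).
* **Reserved names.** The envelope claims `Entity`, `Metadata`, `Node`,
  `Property`, `Link`, `Relation`, `Multiplicity` as top-level Avro type
  names, so dictionary nodes may not use them; generated enum type names
  (`<node>_<property>_values`) are collision-checked against everything
  else. Within a node, a property may not share a name with a link
  destination or be called `id`, because the flat JSON record convention
  would make those ambiguous.

## Container layer

The Avro binary encoding and object container file (magic `Obj\x01`,
metadata map, sync-marker-delimited blocks, `null`/`deflate` codecs) are
implemented in `pfb.avro`, following the Avro 1.11 specification; `deflate`
is the default codec, matching the container format's built-in compression.
Writer output is validated in the test suite against frozen specification
byte vectors and against an independently written decoder
(`tests/avro_oracle.py`), including Parsing-Canonical-Form schema
comparison. Out of scope: snappy/zstd codecs, appends, and read-side schema
resolution between dictionary versions (delegated to the container format's
own evolution rules).

The writer emits entities in caller order; an opt-in strict mode enforces
parent-before-child (every relation target already written). Entity ids
absent on input stay absent — the writer never invents identifiers.

## Validation

`validate_records` reports violations as data, never exceptions, under a
closed rule set: `unknown_node`, `unknown_property`, `type`, `enum`,
`required`, `multiplicity`, `dangling_relation`. Decisions worth noting:

* integer properties reject fractional numbers; integral floats (`44.0`)
  arriving from JSON are coerced to `int` at conversion time; values outside
  the signed 64-bit range are type violations (they could not be encoded);
* booleans are not accepted as integers or numbers;
* from the child side, every multiplicity class except `MANY_TO_MANY`
  admits at most one relation per destination; a relation to an existing
  node with no declared link is reported under `multiplicity`;
* `dangling_relation` is the only cross-record rule and is evaluated within
  the submitted batch; global uniqueness across pre-existing data is out of
  scope (there is no database here);
* an entity naming an unknown node yields that single violation and is not
  inspected further.

All per-record rules are order-insensitive, so violation counts are
invariant under batch permutation. The suite checks the validator
rule-by-rule against an independent brute-force checker
(`tests/validator_oracle.py`).

## Simulator

The simulator stands in for a production data commons so every code path is
exercisable offline. Defaults are the commons-scale study shape: 26 node
types and 399 attributes, 100 records per node. Choices:

* **Topology** — a rooted random tree: node *i* links `MANY_TO_ONE` to a
  uniformly chosen earlier node. Trees satisfy every multiplicity class and
  guarantee acyclicity; a single parent per node matches typical Gen3
  submission graphs.
* **Attributes** — spread as evenly as possible (every node ≥ 1); a
  property is an enum with probability `enum_fraction` (default 0.3, value
  lists sampled from a pool that deliberately includes non-identifier
  strings such as `"Not Reported"`), otherwise uniform over the scalar
  types. A quarter of properties are required, ~15% of the rest nullable.
* **Values** — strings are short phrases over a 20-token vocabulary,
  integers uniform 0–120, numbers uniform 0–100 rounded to 2 decimals,
  dates ISO-formatted. The repetitive text is intentional: it gives
  compression behaviour similar to real clinical exports. No claim of
  clinical realism is made — distributions, correlations and missingness
  of real data are not modelled, so passing tests demonstrate format
  correctness and ordering properties, not statistical fidelity.
* Everything is deterministic per seed; records always fill every property
  and satisfy every link, so simulator output is validator-clean by
  construction (and tested to be).

## Benchmarks

`size_report` serializes one simulated batch four ways — concatenated
per-node JSON arrays, bzip2'd JSON, null-codec PFB, deflate PFB — and
reports bytes; both the uncompressed and compressed JSON sizes are reported
explicitly since "JSON size" is otherwise ambiguous. The meaningful,
machine-independent result is the ordering (PFB < JSON, deflate < null),
which holds for every simulated batch of ≥1000 records across seeds;
absolute bytes depend on the simulator's payloads. `throughput_report`
times full read/write passes (median of 3 repetitions) and is informational
only — rates are hardware-bound and never gate anything.

Desk-scale sizes used throughout the suite and the acceptance script: up to
26 nodes × 100 records per node (2600 records) for round-trip and validator
runs, 13 nodes × 80 records (1040) for size ordering, 6 nodes × 15 for
transform conservation — small enough to run in seconds, large enough that
multi-block container framing and compression are exercised.

## Transforms

`rename_node`, `rename_property`, and `retarget_ontology` are whole-file
copy rewrites (read → edit dictionary → recompile → rewrite entities),
never in-place edits: sync-marker framing makes in-place patching fragile,
and PFB files are snapshot artifacts. Ontology retargeting uses
longest-prefix URI substitution — vocabulary swaps (e.g. CDISC → NCIt)
rewrite whole families of references — applied to node- and property-level
references and to annotation values stored under the key
`ontology_reference`; per-enum-value references are not modelled. All
transforms preserve entity counts and payload value multisets, and a rename
followed by its inverse restores a canonically equal file.

## Known limitations

* One dictionary per file; merging or evolving dictionaries across files is
  not provided.
* The JSON link convention requires link-destination names to be distinct
  from property names within a node (enforced at load).
* `float`-typed Avro fields are readable but never produced; all numbers
  are doubles.
* Throughput numbers are machine-specific by nature.
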