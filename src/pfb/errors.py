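"""Exception hierarchy for the PFB toolkit.

Every error raised by this package derives from :class:`PFBError`, so callers
can catch one type at an API boundary. Validation findings on *data* are not
exceptions — they are :class:`~pfb.model.Violation` values — except in strict
conversion modes, where they are carried by :class:`ValidationError`.
"""

from __future__ import annotations


class PFBError(Exception):
    """Base class for all PFB toolkit errors."""


class ParseError(PFBError):
    """A dictionary document (or mapping file) is malformed."""


class CycleError(PFBError):
    """The link graph of a data dictionary contains a cycle."""


class UnresolvedLinkError(PFBError):
    """A link's destination names a node that does not exist."""


class DuplicateNameError(PFBError):
    """A node, property, or link destination name is declared twice."""


class ConfigError(PFBError):
    """A simulator configuration is inconsistent."""


class EmptyDictionaryError(PFBError):
    """Schema compilation was asked for a dictionary with no nodes."""


class NameCollisionError(PFBError):
    """A name collides with a reserved name or with another sanitized name."""


class UnknownTypeError(PFBError):
    """A property declares a type outside the supported set."""


class UnknownNodeError(PFBError):
    """A node name does not exist in the dictionary/schema at hand."""


class UnknownPropertyError(PFBError):
    """A property name does not exist on the node at hand."""


class SchemaError(PFBError):
    """An Avro schema document is invalid or a datum cannot be encoded."""


class SchemaMismatchError(PFBError):
    """An entity does not conform to the compiled file schema."""


class NotPFBError(PFBError):
    """The file is readable Avro but does not follow the PFB contract."""


class CorruptFileError(PFBError):
    """The file is not a well-formed Avro object container."""


class StrictOrderError(PFBError):
    """Strict parent-before-child emission order was violated."""


class ValidationError(PFBError):
    """Strict-mode conversion aborted; carries the list of violations."""

    def __init__(self, violations):
        self.violations = list(violations)
        preview = "; ".join(v.message for v in self.violations[:3])
        more = len(self.violations) - 3
        if more > 0:
            preview += f" (+{more} more)"
        super().__init__(f"{len(self.violations)} validation violation(s): {preview}")
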