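"""Exception hierarchy.

Two error families matter to callers (and map to distinct CLI exit codes):
``SchemaError`` for malformed documents/configuration and ``DataError`` for
content problems in ontologies and knowledge bases.
"""


class HyevalError(Exception):
    """Base class for all package errors."""


class SchemaError(HyevalError):
    """A structured document (hypothesis, rule set, pattern) is malformed."""


class DataError(HyevalError):
    """Ontology or knowledge-base content is invalid or unresolvable."""
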