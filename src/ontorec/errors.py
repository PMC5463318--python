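"""Exception hierarchy for ontorec.

All errors raised by the library derive from :class:`OntorecError` so callers
can catch one type at the CLI boundary.
"""


class OntorecError(Exception):
    """Base class for all ontorec errors."""


class FormatError(OntorecError):
    """Malformed input file (dictionary, metadata, OBO)."""


class DanglingParentError(FormatError):
    """A parent link references a class id absent from the ontology."""


class StructuralError(OntorecError):
    """The parent graph violates a structural requirement (e.g. a cycle)."""


class ConfigurationError(OntorecError):
    """Invalid weights, constants or run parameters."""


class ContractViolationError(OntorecError):
    """An operation was called outside its documented contract."""


class UndefinedCoverageError(OntorecError):
    """Coverage normalization is undefined because no candidate annotates
    the input; the pipeline should have excluded all ontologies upstream."""
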