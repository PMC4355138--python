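"""Exception hierarchy shared across the package."""


class PhenosearchError(Exception):
    """Base class for all package-specific errors."""


class OboParseError(PhenosearchError):
    """Raised when an OBO file cannot be parsed."""


class OntologyValidationError(PhenosearchError):
    """Raised when a parsed ontology violates structural invariants
    (cyclic is_a, dangling parents, duplicate alt_ids)."""


class UnknownTermError(PhenosearchError):
    """Raised when a term identifier cannot be resolved in the ontology.

    Carries the offending identifier so callers under the lenient policy
    can warn-and-skip instead of aborting.
    """

    def __init__(self, term_id: str, message: str | None = None):
        self.term_id = term_id
        super().__init__(message or f"unknown term identifier: {term_id!r}")


class CorpusFormatError(PhenosearchError):
    """Raised for malformed or empty annotation / association tables."""


class EmptyQueryError(PhenosearchError):
    """Raised when a query retains no usable terms after resolution."""


class EvaluationError(PhenosearchError):
    """Raised for degenerate evaluation inputs (e.g. single-class labels)."""
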