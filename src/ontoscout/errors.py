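"""Exception hierarchy shared across the package."""

from __future__ import annotations


class OntoscoutError(Exception):
    """Base class for all package-specific errors."""


class OntologyFormatError(OntoscoutError):
    """An ontology file could not be parsed; message names the offending construct."""


class CycleError(OntoscoutError):
    """The subclass graph contains a cycle among named classes.

    Every downstream computation (closure, pruning, layout) assumes a DAG,
    so cycles are a hard error rather than being broken silently.
    """

    def __init__(self, cycle: list[str]):
        self.cycle = list(cycle)
        super().__init__(f"cycle among named classes: {' -> '.join(self.cycle)}")


class SchemaError(OntoscoutError):
    """A manifest or index file is missing required columns/keys."""


class ManifestValidationError(OntoscoutError):
    """A manifest violates a semantic constraint (e.g. conflicting titles)."""


class UnknownTermError(OntoscoutError):
    """A query or lookup referenced a term that is not in the graph."""

    def __init__(self, term: str, context: str = ""):
        self.term = term
        msg = f"unknown term: {term}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class UndefinedMetricError(OntoscoutError):
    """Precision/recall is undefined (empty result set or unused term).

    Raised instead of returning 0.0 because zero is a meaningful value in
    the exploration displays.
    """


class CartError(OntoscoutError):
    """Data-cart operation on an id that is absent from the repository/cart."""


class FixtureSpecError(OntoscoutError):
    """A synthetic-fixture specification is infeasible."""


class LayoutError(OntoscoutError):
    """Invalid layout request (unknown sort key, size-zero root, ...)."""


class QueryParseError(OntoscoutError):
    """Malformed canonical query string; carries the offending position."""

    def __init__(self, message: str, position: int = -1):
        self.position = position
        super().__init__(message if position < 0 else f"{message} (at token {position})")
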