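"""Exception hierarchy for kgwalk.

Every error raised by the library derives from :class:`KgwalkError` so that
pipeline drivers can catch stage failures uniformly.
"""


class KgwalkError(Exception):
    """Base class for all kgwalk errors."""


class ParseError(KgwalkError):
    """Malformed RDF input; message names the offending line where known."""


class ValidationError(KgwalkError):
    """A graph invariant or strict-mode declaration check failed."""


class EntityNotFoundError(KgwalkError, LookupError):
    """A node, class, property or token was not found where required."""


class InvalidArgumentError(KgwalkError, ValueError):
    """An argument was outside its documented domain."""


class UnsupportedAxiomError(KgwalkError):
    """An axiom uses a constructor outside the supported EL subset."""


class CorpusFormatError(KgwalkError):
    """A walk-corpus line violates the node/label alternation format."""


class DegenerateVocabularyError(KgwalkError):
    """Skip-gram training with negative sampling needs >= 2 vocabulary tokens."""


class UndefinedSimilarityError(KgwalkError):
    """Cosine similarity is undefined for a zero vector."""


class UndefinedMetricError(KgwalkError):
    """A classification metric is undefined (e.g. single-class labels)."""


class MissingEmbeddingError(KgwalkError):
    """An edge endpoint has no learned vector; message lists offenders."""


class InfeasibleNegativesError(KgwalkError):
    """The type-constrained negative candidate space is too small.

    Attributes
    ----------
    available : int
        Maximum number of negatives that could have been drawn.
    """

    def __init__(self, message: str, available: int):
        super().__init__(message)
        self.available = available
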