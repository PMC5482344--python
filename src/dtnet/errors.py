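"""Exception hierarchy for dtnet.

All library errors derive from :class:`DtnetError` so callers (and the CLI)
can distinguish domain failures from programming errors.
"""


class DtnetError(Exception):
    """Base class for all dtnet errors."""


class InvalidInputError(DtnetError, ValueError):
    """A value, matrix, or parameter violates a precondition."""


class InvalidRecordError(InvalidInputError):
    """An activity record is internally inconsistent (e.g. its measured
    value classifies to a status that contradicts its asserted status)."""


class ConflictError(DtnetError):
    """Two or more records assert contradictory statuses for the same
    drug-target pair under the ``error`` conflict policy."""


class BipartiteError(InvalidInputError):
    """Drug and target label sets overlap, violating bipartiteness."""


class EntityLookupError(DtnetError, KeyError):
    """A drug or target label is absent from the requested side."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep message readable
        return self.args[0] if self.args else ""


class FormatError(DtnetError, ValueError):
    """A file does not conform to the expected edge-list or matrix format."""


class VocabularyError(FormatError):
    """A status token in an edge list is not in the dialect's vocabulary."""


class ConfigError(InvalidInputError):
    """A generator configuration is invalid."""


class UndefinedSimilarityError(InvalidInputError):
    """Cosine similarity requested against a zero-length profile vector."""
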