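"""Exception hierarchy.

All package-raised errors derive from :class:`StateScoreError` so callers can
catch everything with one clause; the CLI maps them to exit status 1 with a
one-line diagnostic.
"""


class StateScoreError(Exception):
    """Base class for all errors raised by statescore."""


class FormatError(StateScoreError):
    """A file on disk does not conform to its declared format."""


class ValidationError(StateScoreError):
    """Input data violates an invariant (negative counts, duplicates, ...)."""


class SchemaError(StateScoreError):
    """A model file is structurally invalid or has an unsupported version."""


class UniverseMismatchError(StateScoreError):
    """A matrix is not aligned to the model's gene universe."""


class TrainingError(StateScoreError):
    """Training preconditions are not met (e.g. a single-class label vector)."""
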