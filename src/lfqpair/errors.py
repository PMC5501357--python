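"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`LfqPairError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class LfqPairError(Exception):
    """Base class for all pipeline errors."""


class FormatError(LfqPairError):
    """A table is structurally malformed (e.g. a required column is missing)."""


class ParseError(LfqPairError):
    """A field could not be parsed; the message cites the offending line."""


class ValidationError(LfqPairError):
    """A record or configuration violates a documented invariant."""


class ConsistencyError(LfqPairError):
    """Records disagree on provenance (donor, condition) or are duplicated."""


class InsufficientDataError(LfqPairError):
    """Too few observations (or zero variance) to estimate population stats."""


class DegenerateIntensityError(LfqPairError):
    """A protein's summed fragment intensity is not positive."""


class ConflictError(LfqPairError):
    """Both differential directions reached the consensus threshold."""
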