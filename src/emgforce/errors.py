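"""Exception hierarchy.

Everything raised by this package derives from :class:`EmgForceError`, so
callers can catch one type at a pipeline boundary.
"""


class EmgForceError(Exception):
    """Base class for all emgforce errors."""


class FormatError(EmgForceError):
    """A file is missing required metadata or cannot be parsed."""


class SchemaError(EmgForceError):
    """Data violate a structural invariant (channel counts, lengths, ...)."""


class SegmentationError(EmgForceError):
    """Constant-force plateaus could not be located in a force trace."""


class DegenerateChannelError(EmgForceError):
    """A channel is unusable (zero power, non-positive normalization ref)."""


class UndefinedCorrelationError(EmgForceError):
    """Pearson correlation requested for a zero-variance signal."""


class IncompatiblePoolError(EmgForceError):
    """A fitted model was applied to a candidate pool with different provenance."""
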