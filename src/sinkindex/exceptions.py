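"""Exception hierarchy for the sinkindex package."""


class SinkIndexError(Exception):
    """Base class for all package errors."""


class FormatError(SinkIndexError):
    """A file could not be parsed as the declared format."""


class MetadataError(SinkIndexError):
    """Required metadata (channel labels, cohort columns) missing or invalid."""


class ValidationError(SinkIndexError):
    """Input values violate a documented contract."""


class DegenerateInputError(SinkIndexError):
    """Input too short / too small / constant for the requested operation."""


class ConfigError(SinkIndexError):
    """Configuration values are inconsistent or unsupported."""


class SingularSystemError(SinkIndexError):
    """Least-squares system has no usable solution (e.g. all-zero window)."""


class StabilityError(SinkIndexError):
    """A simulated state-transition matrix is unstable."""


class EmptyModelError(SinkIndexError):
    """A dynamic network model contains no valid windows."""
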