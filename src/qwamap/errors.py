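"""Exception hierarchy for qwamap.

All qwamap errors derive from :class:`QwamapError` so callers can catch
domain failures without masking programming errors.
"""


class QwamapError(Exception):
    """Base class for all qwamap errors."""


class FormatError(QwamapError):
    """A delimited-text input does not have the expected structure."""


class ValidationError(QwamapError):
    """A table or record violates a domain invariant."""


class ConfigError(QwamapError):
    """A run configuration value is inconsistent or out of range."""


class AssignmentError(QwamapError):
    """A cell cannot be assigned to any ring or sector interval."""


class GenerationError(QwamapError):
    """The synthetic generator could not satisfy its placement constraints."""


class InsufficientDataError(QwamapError):
    """Too few observations for the requested statistic."""
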