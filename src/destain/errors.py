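"""Exception hierarchy shared across the package.

Every validation failure names the offending field or row so that batch
runs fail with actionable messages.
"""


class DestainError(Exception):
    """Base class for all package errors."""


class ValidationError(DestainError):
    """A value violates a documented invariant (message names the field)."""


class ConfigError(ValidationError):
    """Bad or unknown configuration key/value."""


class MetadataError(DestainError):
    """Missing or contradictory acquisition metadata."""


class FormatError(DestainError):
    """A file does not conform to the documented on-disk format."""


class PlacementError(DestainError):
    """Object placement failed under the minimum-separation constraint."""


class DegenerateInputError(DestainError):
    """Input is degenerate for the requested operation (e.g. constant frames)."""
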