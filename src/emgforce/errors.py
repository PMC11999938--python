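"""Exception types raised across the pipeline.

All inherit from :class:`EmgForceError` so callers can catch the package's
failures with a single except clause; validation problems additionally
inherit from ``ValueError`` to behave well in generic code.
"""


class EmgForceError(Exception):
    """Base class for all emgforce errors."""


class ValidationError(EmgForceError, ValueError):
    """Invalid argument or configuration value."""


class UnknownModeError(ValidationError):
    """Force mode / group / strategy label not recognized."""


class ChannelIndexError(ValidationError):
    """Channel index outside the recording's grid."""


class RecordingUnusableError(EmgForceError):
    """Too many defective channels to repair the recording."""


class DegenerateDecompositionError(EmgForceError):
    """NMF produced an all-zero primary activation mode."""


class TrainingError(EmgForceError):
    """Non-finite loss or otherwise failed optimization."""


class FormatError(EmgForceError, ValueError):
    """On-disk data does not match its declared layout."""
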