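"""Exception hierarchy shared across the package."""


class PhysioSyncError(Exception):
    """Base class for all package errors."""


class ConfigError(PhysioSyncError, ValueError):
    """Invalid configuration or generator parameters."""


class FormatError(PhysioSyncError, ValueError):
    """Malformed on-disk data (names the first offending line where possible)."""


class DataQualityError(PhysioSyncError):
    """Data too degraded to analyse (e.g. majority of beats flagged as artifacts)."""
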