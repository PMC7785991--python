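"""Exception hierarchy. Every named error the CLI reports derives from ZfecgError."""


class ZfecgError(Exception):
    """Base class for all package errors."""


class ConfigError(ZfecgError):
    """Invalid simulation or analysis configuration."""


class NoSignalError(ZfecgError):
    """Trace is flat, empty or all-NaN; no detection is possible."""


class InsufficientBeatsError(ZfecgError):
    """Fewer beats than the operation requires (e.g. < 2 for intervals)."""


class InsufficientDataError(ZfecgError):
    """Fewer intervals / samples than the operation requires."""


class DegenerateVarianceError(ZfecgError):
    """Both samples constant and identical: the t statistic is undefined."""


class MissingConditionError(ZfecgError):
    """A qPCR condition (control or treatment) has no samples."""


class SubjectMismatchError(ZfecgError):
    """Subject ids are inconsistent across per-recording inputs."""
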