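"""Exception hierarchy.

All package errors derive from :class:`HeadlagError` so callers can catch
one base class; the CLI maps subclasses onto exit codes.
"""


class HeadlagError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(HeadlagError):
    """A sequence or model file violates the keypoint schema."""


class ConfigError(HeadlagError):
    """Invalid or unknown configuration key/value."""


class DegenerateGeometryError(HeadlagError):
    """A geometric construction is undefined (zero-length axis, parallel axes)."""


class DegenerateRangeError(HeadlagError):
    """A coordinate axis has zero range and cannot be min-max normalized."""

    def __init__(self, axis: str, message: str | None = None):
        self.axis = axis
        super().__init__(message or f"zero coordinate range on axis {axis!r}")


class AdapterContractError(HeadlagError):
    """A pluggable 2D-to-3D lifting adapter violated its contract."""


class PipelineStageError(HeadlagError):
    """An error raised inside a named preprocessing stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"preprocessing stage {stage!r} failed: {original}")
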