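"""Exceptions shared across the package."""


class PcaRedoxError(Exception):
    """Base class for package-specific errors."""


class NoValidDataError(PcaRedoxError):
    """A series contains no valid (unflagged, above-threshold) measurement."""


class InsufficientDataError(PcaRedoxError):
    """Fewer valid points than the requested fit needs."""


class DegenerateFitError(PcaRedoxError):
    """The regression design is singular (e.g. zero variance in time)."""


class SchemaError(PcaRedoxError):
    """An input table violates the documented column/value contract."""
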