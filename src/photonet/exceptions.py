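"""Exception hierarchy.

All photonet errors derive from :class:`PhotonetError` so callers can catch
the whole family; the subclasses distinguish bad input files, invalid data,
bad parameters, and numerical failures (exit codes 2 / 1 / 1 / 2 in the CLI).
"""


class PhotonetError(Exception):
    """Base class for all photonet errors."""


class FormatError(PhotonetError):
    """An external file does not conform to its declared format."""


class ValidationError(PhotonetError):
    """In-memory data violates a domain invariant."""


class ParameterError(PhotonetError, ValueError):
    """A user-supplied parameter is outside its documented range."""


class ComputationError(PhotonetError):
    """A computation is undefined for the given inputs (e.g. inactive positive control)."""


class FitError(PhotonetError):
    """Nonlinear fitting failed or was attempted on insufficient data."""
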