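"""Exception hierarchy shared by every pipeline stage.

All validation failures raise a subclass of :class:`MaldiKDError` so callers
(and the CLI) can distinguish data problems from programming errors.
"""


class MaldiKDError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(MaldiKDError, ValueError):
    """An argument is outside its documented domain."""


class ParseError(MaldiKDError):
    """A text input could not be parsed; the message names the location."""


class EmptySpectrumError(MaldiKDError):
    """A spectrum source contained zero data points."""


class StructureError(MaldiKDError):
    """An on-disk dataset layout violates the expected structure."""


class ConflictError(MaldiKDError):
    """Identifiers collide where uniqueness is required."""


class DegenerateSpectrumError(MaldiKDError):
    """A spectrum cannot be normalized (zero total or median intensity)."""


class EmptySelectionError(MaldiKDError):
    """A restriction operation left no data."""


class ConsistencyError(MaldiKDError):
    """Two artifacts that must agree (e.g. tree leaves vs. matrix axes) do not."""


class UndefinedTestError(MaldiKDError):
    """A statistical test is undefined on the given table (degenerate margins)."""
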