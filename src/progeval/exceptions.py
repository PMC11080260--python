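"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`ProgevalError`,
so callers can catch one type at a pipeline boundary.  Validation errors also
derive from :class:`ValueError` to behave well in generic code.
"""


class ProgevalError(Exception):
    """Base class for all errors raised by progeval."""


class InvalidIndicatorError(ProgevalError, ValueError):
    """An indicator violates its invariants (E <= 0, O > E, W <= 0, ...)."""


class InvalidDimensionError(ProgevalError, ValueError):
    """A dimension is empty or carries a non-positive weight."""


class InvalidConfigError(ProgevalError, ValueError):
    """An evaluation/generator/model configuration is inconsistent."""


class InvalidRecordError(ProgevalError, ValueError):
    """A respondent record violates the Likert scale it claims to follow."""


class ZeroCellError(ProgevalError, ValueError):
    """A 2x2 table contains an empty cell and no continuity correction was requested."""


class DegenerateOutcomeError(ProgevalError, ValueError):
    """The outcome variable is constant; no association model can be fitted."""


class ParseError(ProgevalError, ValueError):
    """A CSV/YAML input failed validation; carries the file and row it failed on."""

    def __init__(self, message: str, path=None, row=None):
        self.path = path
        self.row = row
        where = ""
        if path is not None:
            where += f"{path}"
        if row is not None:
            where += f", row {row}"
        super().__init__(f"{where}: {message}" if where else message)
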