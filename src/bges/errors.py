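"""Exception hierarchy.

All errors raised by this package derive from :class:`BgesError` so callers
can catch one type; subtypes distinguish bad data values, bad configuration,
identifier misalignment and file parsing problems (the CLI maps each to a
distinct exit code).
"""


class BgesError(Exception):
    """Base class for all package errors."""


class DataError(BgesError, ValueError):
    """Invalid data values (non-finite entries, duplicates, ragged input)."""


class ConfigurationError(BgesError, ValueError):
    """Invalid analysis configuration (empty condition, bad option value)."""


class AlignmentError(BgesError, ValueError):
    """Gene/sample identifier mismatch between two aligned objects."""


class ParseError(BgesError, ValueError):
    """Malformed input file; message names the file and line where known."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}, line {line}]" if line is not None else f" [{path}]"
        super().__init__(message + loc)
        self.path = path
        self.line = line
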