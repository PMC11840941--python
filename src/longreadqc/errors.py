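"""Exception hierarchy shared by all longreadqc modules.

Every error raised by the package derives from :class:`LongReadQCError`
so CLI code can map failures onto stable exit codes (1 usage, 2 parse).
"""


class LongReadQCError(Exception):
    """Base class for all longreadqc errors."""


class ParseError(LongReadQCError):
    """Malformed input file.

    Carries optional ``line`` (1-based line number) and ``record``
    (read identifier) context for actionable messages.
    """

    def __init__(self, message: str, *, line: int | None = None,
                 record: str | None = None):
        ctx = []
        if record is not None:
            ctx.append(f"read {record!r}")
        if line is not None:
            ctx.append(f"line {line}")
        if ctx:
            message = f"{message} ({', '.join(ctx)})"
        super().__init__(message)
        self.line = line
        self.record = record


class UnsupportedDialectError(ParseError):
    """Tabular input whose header does not match any known column alias."""


class MalformedTagError(ParseError):
    """Inconsistent SAM auxiliary tag (MM/ML, mv/ts)."""


class UndefinedStatisticError(LongReadQCError):
    """A statistic requested on an empty input where it has no value."""


class ConfigError(LongReadQCError):
    """Invalid user-supplied configuration (thresholds, generator specs)."""


class BoundsError(LongReadQCError):
    """A requested range lies outside the data."""
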