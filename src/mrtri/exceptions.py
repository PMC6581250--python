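"""Exception hierarchy for mrtri.

All errors raised on bad user input derive from :class:`MrtriError` so callers
can catch one base class; subclasses distinguish schema problems (wrong
columns), per-row validation failures, and analysis-stage degeneracies.
"""


class MrtriError(Exception):
    """Base class for all mrtri errors."""


class SchemaError(MrtriError):
    """A required column or field is missing from an input table."""


class RowParseError(MrtriError):
    """A data row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"{message} (line {line})" if line is not None else message)


class ValidationError(MrtriError):
    """A parsed value violates a domain invariant (e.g. SE <= 0)."""


class HarmonisationError(MrtriError):
    """Harmonisation cannot proceed (e.g. empty rsid intersection)."""


class DegenerateInstrumentError(MrtriError):
    """An instrument has zero effect on the exposure; the Wald ratio is undefined."""


class CollinearityError(MrtriError):
    """Design matrix is rank deficient (e.g. identical maternal/fetal dosages)."""


class UnitMismatchError(MrtriError):
    """A rescaling was requested between incompatible units."""


class ConfigError(MrtriError):
    """A run configuration is invalid or an analysis precondition fails."""
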