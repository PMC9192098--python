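"""Exception hierarchy shared across the toolkit."""


class SttkitError(Exception):
    """Base class for all toolkit errors."""


class LeadNotFoundError(SttkitError, KeyError):
    """A requested/required lead label is absent from a record."""

    def __init__(self, lead: str):
        super().__init__(f"lead not found: {lead!r}")
        self.lead = lead


class ParseError(SttkitError, ValueError):
    """Malformed delimited input; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class SchemaError(SttkitError, ValueError):
    """A table is missing or contains unexpected columns."""


class RecordTooShortError(SttkitError, ValueError):
    """A record is too short for the requested operation."""


class InsufficientBeatsError(SttkitError, ValueError):
    """Fewer beats detected than the operation requires."""


class DelineationError(SttkitError, ValueError):
    """ST-T delineation failed to produce enough valid beats."""


class EmptySegmentSetError(SttkitError, ValueError):
    """Splicing was requested with no segments."""


class DegenerateSeriesError(SttkitError, ValueError):
    """A series has zero standard deviation."""


class UndefinedEntropyError(SttkitError, ValueError):
    """Sample entropy undefined: no template matches at m or m+1."""


class ShiUndefinedError(SttkitError, ValueError):
    """Spatial heterogeneity index undefined: no valid neighbour pairs."""


class ThiUndefinedError(SttkitError, ValueError):
    """Temporal heterogeneity index undefined (e.g. all-zero lead)."""


class ConfigError(SttkitError, ValueError):
    """Invalid or unknown configuration keys/values."""
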