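"""Exception hierarchy shared across the package."""


class PPSError(Exception):
    """Base class for all ppspace errors."""


class DesignError(PPSError):
    """An experiment design violates its invariants."""


class SchemaError(PPSError):
    """A trial file does not match the expected column schema."""


class TrialValidationError(PPSError):
    """One or more trial records violate the schema invariants.

    Carries ``rows``: a list of ``(row_number, message)`` pairs so callers can
    report every offending row instead of the first one.
    """

    def __init__(self, rows):
        self.rows = list(rows)
        lines = "; ".join(f"row {r}: {m}" for r, m in self.rows[:20])
        more = "" if len(self.rows) <= 20 else f" (+{len(self.rows) - 20} more)"
        super().__init__(f"{len(self.rows)} invalid trial(s): {lines}{more}")


class UndefinedFitError(PPSError):
    """A regression is requested on data that cannot determine it."""


class EmptyCellError(PPSError):
    """A distance cell required for a profile contains no trials."""


class DegenerateProfileError(PPSError):
    """All per-distance means are equal; min-max normalization is undefined."""


class ConfigError(PPSError):
    """An analysis configuration is missing required entries."""
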