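"""Exception hierarchy shared across the package."""


class CVDTrendsError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CVDTrendsError, ValueError):
    """A numeric input is non-finite, out of range, or of the wrong shape."""


class ConfigError(CVDTrendsError, ValueError):
    """A coefficient table, recalibration table, scenario, or run config is invalid."""


class ScoringIneligibleError(CVDTrendsError):
    """A profile is missing a component required by the requested score variant
    (complete-case contract: scoring never imputes)."""


class CoverageError(CVDTrendsError, LookupError):
    """An attained age during follow-up falls outside the recalibration table."""

    def __init__(self, message: str, year: int | None = None):
        super().__init__(message)
        self.year = year
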