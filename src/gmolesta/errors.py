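"""Exception hierarchy shared across the package."""


class GmolestaError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(GmolestaError, ValueError):
    """An argument violates a documented precondition."""


class TemperatureGapError(GmolestaError):
    """A daily temperature series has a missing day.

    Degree-day accumulation requires consecutive days; gaps are never
    imputed because silent imputation would bias cumulative degree-days.
    """

    def __init__(self, first_missing):
        self.first_missing = first_missing
        super().__init__(f"temperature series has a gap; first missing day: {first_missing}")


class CoverageError(GmolestaError):
    """An observation date falls outside the available degree-day series."""


class ConstraintViolationError(GmolestaError, ValueError):
    """A parameter set violates a model constraint (e.g. proportions > 1)."""


class DegenerateDataWarning(UserWarning):
    """Emitted when data carry too little signal for a meaningful estimate."""
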