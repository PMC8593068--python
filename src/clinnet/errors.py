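"""Exception hierarchy shared across the package."""


class ClinnetError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ClinnetError, ValueError):
    """An input value violates a documented precondition or invariant."""


class MissingDataError(ClinnetError, ValueError):
    """A selection or lookup produced no usable records."""


class UndefinedStatisticError(ClinnetError, ValueError):
    """A statistic is undefined for the given data (e.g. zero variance,
    zero denominator count) and no imputation was requested."""


class TrialDataParseError(ClinnetError, ValueError):
    """A trial-data CSV failed validation.

    Carries the offending 1-based file line numbers in ``lines``.
    """

    def __init__(self, message: str, lines: list[int] | None = None):
        super().__init__(message)
        self.lines = lines or []
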