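"""Exception hierarchy shared across the pipeline."""


class FWAgingError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FWAgingError):
    """A generator or pipeline configuration is invalid."""


class EmptyInputError(FWAgingError):
    """An operation received an empty collection where data is required."""


class UndefinedStatisticError(FWAgingError):
    """A statistic is undefined for the given input (zero margin/variance)."""


class FactorLookupError(FWAgingError, KeyError):
    """A named factor, term, region or year is unknown."""


class RankDeficiencyError(FWAgingError):
    """The design matrix is not full rank."""


class SeparationError(FWAgingError):
    """The logistic likelihood is unbounded (perfect/quasi separation).

    Carries ``diagnostics``: a mapping with the offending term names and
    their runaway coefficient magnitudes, when identifiable.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class StepwiseError(FWAgingError):
    """A stepwise fit failed; ``partial_trace`` holds the steps so far."""

    def __init__(self, message: str, partial_trace=None):
        super().__init__(message)
        self.partial_trace = partial_trace
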