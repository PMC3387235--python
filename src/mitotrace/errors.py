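"""Exception hierarchy.

Every error carries a machine-readable ``category`` used by the CLI to set
exit metadata, so downstream tooling can branch on failure class without
parsing messages.
"""


class MitoTraceError(Exception):
    """Base class for all package errors."""

    category = "error"


class TraceFormatError(MitoTraceError):
    """Malformed trace/event/config file (missing header, bad columns)."""

    category = "format error"


class OrderingError(MitoTraceError):
    """Time stamps decrease beyond tolerance."""

    category = "ordering error"


class InsufficientDataError(MitoTraceError):
    """Too few samples/rows/points for the requested operation."""

    category = "insufficient-data error"


class VocabularyError(MitoTraceError):
    """Compound label outside the controlled vocabulary."""

    category = "vocabulary error"


class ConfigurationError(MitoTraceError):
    """Invalid or inconsistent run configuration."""

    category = "configuration error"


class CalibrationError(MitoTraceError):
    """Calibration could not be established (missing events, inverted endpoints)."""

    category = "calibration error"


class SaturationError(MitoTraceError):
    """Signal at or above the calibrated ceiling."""

    category = "saturation error"


class BelowFloorError(MitoTraceError):
    """Signal below the calibrated floor."""

    category = "below-floor error"


class DomainError(MitoTraceError):
    """Argument outside the mathematical domain of an operation."""

    category = "domain error"


class EventError(MitoTraceError):
    """A required event (e.g. the ADP addition) is absent."""

    category = "event error"


class FitError(MitoTraceError):
    """Nonlinear fit failed to converge; carries the best residual seen."""

    category = "fit-failure error"

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


class InconsistentInputError(MitoTraceError):
    """Speciation inversion produced a total outside physical bounds."""

    category = "inconsistent-input error"


class HeterogeneityError(MitoTraceError):
    """Bolus amounts differ; capacity counting requires uniform additions."""

    category = "heterogeneity error"


class UndefinedRatioError(MitoTraceError):
    """Denominator of a ratio (control rate, controlled-state flux) is zero."""

    category = "undefined-ratio error"
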