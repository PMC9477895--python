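"""Exception hierarchy for chart digitization and cohort analytics."""


class IopChartError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(IopChartError):
    """Invalid configuration, template, or distribution specification."""


class NoFrameFound(IopChartError):
    """No contour resembling the plot frame covers enough of the page."""


class TimeAxisAmbiguous(IopChartError):
    """The number of detected vertical time lines is not exactly five."""

    def __init__(self, found: int, message: str | None = None):
        self.found = found
        super().__init__(message or f"expected 5 time lines, found {found}")


class OutOfFrame(IopChartError):
    """A pixel coordinate lies outside the calibrated plot frame."""


class DateUnparsed(IopChartError):
    """The date field does not segment into the expected digit pattern."""


class InsufficientData(IopChartError):
    """Too few observations to derive the requested summary."""


class InvalidBloodPressure(IopChartError):
    """Systolic pressure must exceed diastolic pressure."""


class DegenerateLabels(IopChartError):
    """Both outcome classes are required but only one is present."""


class StatisticUndefined(IopChartError):
    """The requested statistic is undefined for this input (e.g. zero variance)."""


class InfeasibleParams(IopChartError):
    """Requested (prevalence, phi) combination violates the Frechet bounds."""


class SeparationWarning(UserWarning):
    """Complete separation encountered in a logistic fit; odds ratio is infinite."""
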