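"""Exception hierarchy shared across the pipeline.

Every error raised on purpose derives from :class:`RiskImageryError`, so
callers can catch pipeline failures without swallowing programming errors.
"""


class RiskImageryError(Exception):
    """Base class for all errors raised by riskimagery."""


class SchemaError(RiskImageryError):
    """A declared column/channel is missing or unknown."""


class IntegrityError(RiskImageryError):
    """Data violate a structural invariant (bounds, duplicates, overlaps)."""


class LayoutError(RiskImageryError):
    """A blood-pressure series deviates from the canonical phase layout."""


class DomainViolationError(RiskImageryError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class DegenerateDataError(RiskImageryError):
    """Zero variance / zero power makes the requested statistic undefined."""


class SampleSizeError(RiskImageryError):
    """Too few subjects for the requested analysis."""


class DesignError(RiskImageryError):
    """Unbalanced or incomplete within-subject design."""


class SegmentError(RiskImageryError):
    """An EEG segment is too short to epoch."""


class ParameterError(RiskImageryError, ValueError):
    """An analysis parameter is invalid (e.g. filter edge beyond Nyquist)."""


class CoverageError(RiskImageryError):
    """A requested electrode/condition is absent from the data."""


class RankError(RiskImageryError):
    """The fixed-effects design matrix is rank deficient."""


class ConvergenceError(RiskImageryError):
    """The mixed-model optimizer failed to converge.

    Carries the optimizer result (``.trace``) for diagnosis.
    """

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class ConfigError(RiskImageryError):
    """A generator or run configuration is internally inconsistent."""
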