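"""Exception hierarchy for the wristcompact pipeline."""


class WristCompactError(Exception):
    """Base class for all package-specific errors."""


class MaskSetError(WristCompactError):
    """A wrist mask set is incomplete, inconsistent, or unreadable."""


class EmptyMaskError(MaskSetError):
    """A bone mask contains no foreground pixels where one is required."""


class DegenerateConfigurationError(WristCompactError):
    """All bone centroids coincide, so the bounding-box diagonal is zero.

    Raw (unnormalized) metrics computed before the failure are attached as
    ``raw_metrics`` so cohort runs can report what was measurable.
    """

    def __init__(self, message: str, raw_metrics: dict | None = None):
        super().__init__(message)
        self.raw_metrics = raw_metrics or {}


class ZeroVarianceError(WristCompactError):
    """A correlation input vector is constant."""


class DesignError(WristCompactError):
    """Unknown analysis design, or a design selected no observations."""


class DataJoinError(WristCompactError):
    """Metric and clinical-score tables cannot be joined consistently."""


class GenerationError(WristCompactError):
    """Synthetic-wrist parameters produce an invalid (e.g. off-grid) bone."""
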