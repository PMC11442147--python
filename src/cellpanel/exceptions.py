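"""Exception hierarchy for the cellpanel pipeline.

Every stage raises a subclass of :class:`CellPanelError` so callers can
distinguish pipeline failures from programming errors.
"""


class CellPanelError(Exception):
    """Base class for all cellpanel errors."""


class AnnotationKeyError(CellPanelError, KeyError):
    """A required per-cell annotation column is missing."""


class ConditionCardinalityError(CellPanelError, ValueError):
    """The condition column does not hold exactly two distinct values."""


class PatientConsistencyError(CellPanelError, ValueError):
    """A patient carries cells with more than one condition label."""


class AlreadyNormalizedError(CellPanelError, ValueError):
    """normalize_counts was called on data that is already normalized."""


class EmptyResultError(CellPanelError, ValueError):
    """A filter removed everything; thresholds may need relaxing."""


class InsufficientCohortError(CellPanelError, ValueError):
    """Too few patients per condition for a patient-wise split."""


class UnknownIdError(CellPanelError, KeyError):
    """A requested patient / cell-type / gene id does not exist."""


class DegenerateCurveError(CellPanelError, ValueError):
    """An accuracy curve has too few points for elbow detection."""


class SingleClassError(CellPanelError, ValueError):
    """Labels contain a single class where two are required."""


class MissingGenesError(CellPanelError, KeyError):
    """Panel genes are absent from a prediction dataset."""


class ScoringError(CellPanelError, RuntimeError):
    """All scoring repeats for a cell type failed."""


class ConfigError(CellPanelError, ValueError):
    """A configuration object is degenerate or inconsistent."""
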