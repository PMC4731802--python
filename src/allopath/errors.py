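"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`AllopathError`, so callers (and the
CLI, which maps validation errors to exit code 1 and runtime errors to 2)
can distinguish user mistakes from genuine failures.
"""


class AllopathError(Exception):
    """Base class for all package errors."""


class FormatError(AllopathError):
    """A file could not be parsed; the message names the offending record."""


class EmptyInputError(AllopathError):
    """An input file or selection contained nothing usable."""


class DimensionError(AllopathError):
    """Array / atom-count shapes are inconsistent."""


class AlignmentError(AllopathError):
    """Two objects that must share a site or node list do not."""


class AnnotationError(AllopathError):
    """Required metadata (domain labels, residue types, heavy atoms) missing."""


class InsufficientFramesError(AllopathError):
    """An ensemble statistic was requested with too few frames."""


class DegenerateFitError(AllopathError):
    """Rigid-body superposition is ill-posed (fewer than 3 non-collinear sites)."""


class SettingsError(AllopathError):
    """Estimator or replica settings are incompatible."""


class SpecError(AllopathError):
    """A synthetic-ensemble specification is invalid (e.g. non-PSD covariance)."""


class NumericError(AllopathError):
    """A closed-form evaluation hit a singular or ill-conditioned case."""


class PartitionError(AllopathError):
    """A community partition does not cover the node set exactly once."""


class DataError(AllopathError):
    """Trajectory data contain non-finite or otherwise unusable values."""


class ValidationError(AllopathError):
    """A run configuration failed validation before any compute."""
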