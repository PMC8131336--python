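"""Exception hierarchy.

Every error raised by this package derives from :class:`LsvarError`, so
callers can catch one base class at pipeline boundaries while the leaf
classes keep failure modes distinguishable (and are what the CLI maps to
exit codes).
"""


class LsvarError(Exception):
    """Base class for all package errors."""


class InvalidMeasurementError(LsvarError):
    """An attenuation measurement violates its invariants."""


class InvalidVolumeError(LsvarError):
    """A segmental volume is zero, negative, or otherwise unusable."""


class InvalidScoreError(LsvarError):
    """An ordinal score value outside its admissible set."""


class EmptyRoiError(LsvarError):
    """A region-of-interest statistic was requested for an empty region."""


class MeasurementError(LsvarError):
    """A labeled volume is missing regions required for measurement."""


class CapacityError(LsvarError):
    """Phantom targets cannot be voxelized inside the requested grid."""


class ConfigError(LsvarError):
    """A configuration object carries impossible parameters."""


class DegenerateRocError(LsvarError):
    """ROC analysis requested with only one class present."""


class UndefinedVarianceError(LsvarError):
    """AUC variance undefined (fewer than two subjects per class)."""


class UndefinedMetricError(LsvarError):
    """Sensitivity/specificity undefined because a class is empty."""


class UndefinedIccError(LsvarError):
    """ICC undefined because the ratings carry no variance at all."""


class SchemaError(LsvarError):
    """A cohort table does not conform to the documented schema."""


class DegenerateStudyError(LsvarError):
    """The cohort has a single stiffness class after thresholding."""
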