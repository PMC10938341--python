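"""Exception hierarchy for surfqc.

Every error raised by the package derives from :class:`SurfQCError` so callers
can catch package failures with a single except clause while still
distinguishing format problems from statistical or configuration ones.
"""


class SurfQCError(Exception):
    """Base class for all surfqc errors."""


class FormatError(SurfQCError):
    """A file could not be parsed as the expected on-disk format."""


class DimensionalityError(FormatError):
    """A volume was not a 3-D scalar grid."""


class IntegrityError(SurfQCError):
    """Parsed data violates a structural invariant (e.g. face index out of range)."""


class SchemaError(SurfQCError):
    """A tabular input is missing required columns/roles."""


class VocabularyError(SurfQCError):
    """A categorical value is outside the declared vocabulary."""


class UniquenessError(IntegrityError):
    """A key that must be unique is duplicated."""


class ConfigError(SurfQCError):
    """Invalid configuration parameters."""


class ThresholdError(SurfQCError):
    """A threshold selected no data (or otherwise cannot be applied)."""


class EmptyInputError(SurfQCError):
    """An operation requiring at least one value received none."""


class DegenerateInputError(SurfQCError):
    """Input is technically valid but statistically degenerate (e.g. zero variance)."""


class AlignmentError(SurfQCError):
    """Two participant-aligned sequences do not align."""


class CollisionError(SurfQCError):
    """Two distinct inputs produced the same anonymized hash."""


class DomainError(SurfQCError):
    """A numeric argument is outside its mathematical domain."""


class DesignError(SurfQCError):
    """A model design matrix is rank deficient or otherwise unusable."""


class StrategyError(SurfQCError):
    """A case-control QC strategy emptied a diagnostic group or is invalid."""


class GeometryError(SurfQCError):
    """A mesh operation cannot be performed on this geometry."""
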