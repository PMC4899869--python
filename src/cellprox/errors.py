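"""Exception hierarchy.

Every distinct failure mode named in the I/O, detection and scoring
contracts gets its own class so callers (and the CLI) can report precise,
actionable errors instead of bare ValueErrors.
"""


class CellproxError(Exception):
    """Base class for all package-specific errors."""


class MissingFileError(CellproxError):
    """Input path does not exist or is not readable."""


class UnreadableImageError(CellproxError):
    """File exists but cannot be decoded as a supported image."""


class ChannelAbsentError(CellproxError):
    """Requested channel is not present in the image / channel map."""


class MaskShapeError(CellproxError):
    """Mask raster shape does not match the associated image."""


class EmptyValidRegionError(CellproxError):
    """After exclusions, no valid pixel remains for analysis."""


class PolygonError(CellproxError):
    """Malformed (e.g. self-intersecting) region polygon."""


class PointSchemaError(CellproxError):
    """Point table is missing required columns or has non-numeric values."""


class OutOfBoundsError(CellproxError):
    """A point coordinate lies outside the raster bounds of its sample."""


class EmptySourceError(CellproxError):
    """Nearest-neighbour query requested with no source points."""


class EmptyTargetError(CellproxError):
    """Nearest-neighbour query requested with no target points / region."""


class DegenerateNullError(CellproxError):
    """Monte-Carlo null has zero spread; the association score is undefined."""


class ModeMismatchError(CellproxError):
    """Observed summary and null were computed under different modes."""


class DegenerateImageError(CellproxError):
    """Image content cannot support the requested operation
    (e.g. Otsu thresholding of an all-zero masked image)."""


class GenerationFailureError(CellproxError):
    """Rejection sampling failed to place a point within the attempt cap."""


class ConfigError(CellproxError):
    """Run configuration violates a downstream precondition."""
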