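"""Exception hierarchy for the myosono pipeline.

Every stage raises a subclass of :class:`MyosonoError` so callers can catch
pipeline failures without masking programming errors.
"""


class MyosonoError(Exception):
    """Base class for all myosono errors."""


class ManifestSchemaError(MyosonoError):
    """Manifest is missing required columns or is otherwise malformed."""


class ManifestValueError(MyosonoError):
    """A manifest row carries an unrecognised token (diagnosis, muscle, ...)."""


class MissingFileError(MyosonoError):
    """One or more files referenced by the manifest do not exist."""


class DimensionMismatchError(MyosonoError):
    """Image/mask shapes disagree, or a feature vector has the wrong length."""


class EmptyRegionError(MyosonoError):
    """The requested tissue label has zero pixels in the mask."""


class DegenerateCohortError(MyosonoError):
    """Cohort filtering left only one class."""


class DegenerateRatioError(MyosonoError):
    """Muscle/fat echointensity ratio is undefined (fat mean is zero)."""


class InsufficientDataError(MyosonoError):
    """Too few pixels to fit a distribution."""


class DegenerateTextureError(MyosonoError):
    """Region is constant: speckle statistics are undefined."""


class InsufficientPairsError(MyosonoError):
    """No co-occurring in-region pixel pair exists for any GLCM direction."""


class FeatureExtractionError(MyosonoError):
    """A feature component failed; message identifies the offending record."""


class DegenerateTrainingError(MyosonoError):
    """Training set contains fewer than two examples of some class."""


class UndefinedMetricError(MyosonoError):
    """Confusion counts lack a truth class, so the metric set is undefined."""


class ConfigurationError(MyosonoError):
    """Invalid pipeline / cross-validation configuration."""


class FoldDegeneracyError(MyosonoError):
    """A cross-validation fold contains a single truth class."""


class GeometryError(MyosonoError):
    """Phantom geometry is invalid (e.g. fat band rounds to zero rows)."""


class OverwriteError(MyosonoError):
    """Output directory exists and is non-empty; pass force to overwrite."""
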