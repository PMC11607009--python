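"""Exception hierarchy.

Every failure mode that callers are expected to distinguish gets its own
class; plain ``ValueError`` is reserved for programming errors (wrong array
shapes, negative counts) that no recovery path cares about.
"""


class FidkitError(Exception):
    """Base class for all fidkit-specific errors."""


class GeometryError(FidkitError):
    """Device geometry violates a mechanical invariant."""


class NoMarkersFoundError(FidkitError):
    """Thresholding/filtering left no marker candidates in the volume."""


class ThresholdSaturationError(FidkitError):
    """The intensity threshold selects (almost) the whole volume."""


class ClassificationError(FidkitError):
    """Marker points could not be split into collector/wheel/target roles."""


class AmbiguousAssignmentError(ClassificationError):
    """Two wheel labels fit the observed radii equally well."""


class DegenerateAxisError(FidkitError):
    """Axis fit is undefined (coincident or insufficient points)."""


class DegenerateOrbitError(FidkitError):
    """Home marker lies on the rotation axis; its orbit collapses."""


class DegenerateFiducialsError(FidkitError):
    """Fiducial set is collinear or too small for a rigid fit / TRE model."""


class UndefinedEstimatorError(FidkitError):
    """An error estimator was requested outside its domain (e.g. N <= 2)."""
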