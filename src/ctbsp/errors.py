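"""Exception hierarchy for the pipeline.

Stage-specific errors subclass :class:`CTBSPError` so pipeline drivers can
attach stage context while callers still catch one base type.
"""


class CTBSPError(Exception):
    """Base class for all package errors."""


class FormatError(CTBSPError):
    """Unreadable or unsupported file format."""


class MetadataError(CTBSPError):
    """Volume file lacks required geometry metadata (spacing/affine)."""


class ValidationError(CTBSPError):
    """Input violates a documented precondition (duplicates, non-finite...)."""


class AlignmentError(CTBSPError):
    """Mask and volume shapes disagree."""


class EmptySelectionError(CTBSPError):
    """An operation that needs a non-empty voxel selection got none."""


class ConfigurationError(CTBSPError):
    """Missing required configuration element (e.g. no muscle rod)."""


class FitError(CTBSPError):
    """A regression segment is under-determined or x is constant."""


class InversionError(CTBSPError):
    """HU→density mapping cannot be inverted (non-positive slope)."""


class EmptySegmentError(CTBSPError):
    """Thresholding produced no foreground voxels."""


class TopologyError(CTBSPError):
    """No enclosed cavity exists inside the bone shell."""


class DegeneracyError(CTBSPError):
    """Degenerate geometry (collinear plane points, coincident landmarks)."""


class DegenerateDensityError(CTBSPError):
    """A mask contains only air voxels, so no tissue density is defined."""


class InsufficientDataError(CTBSPError):
    """Cohort-level statistics require more subjects than were provided."""


class UnsupportedGeometryError(CTBSPError):
    """Phantom primitives overlap partially (only containment is analytic)."""
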