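"""Exception and warning hierarchy for foliakit.

All errors raised on bad user input derive from :class:`FoliakitError` so
callers can catch one base class; warnings derive from
:class:`FoliakitWarning` and are emitted through the standard ``warnings``
machinery.
"""


class FoliakitError(Exception):
    """Base class for all foliakit errors."""


class FormatError(FoliakitError):
    """A file could not be parsed as the requested format."""


class UnsupportedGeometryError(FormatError):
    """Surface file contains non-triangular faces or other unsupported geometry."""


class LabelLookupError(FoliakitError):
    """A label/color present in the data has no entry in the label table."""


class DimensionalityError(FoliakitError):
    """A volume has the wrong number of dimensions."""


class AffineError(FoliakitError):
    """A voxel-to-world affine is singular or otherwise invalid."""


class TopologyError(FoliakitError):
    """A surface is not closed / not consistently oriented."""


class PipelineError(FoliakitError):
    """An atlas pipeline postcondition failed (e.g. unlabeled interior voxels)."""


class ApportionmentError(FoliakitError):
    """Patch counts cannot be apportioned (e.g. region with zero area)."""


class SeedingError(FoliakitError):
    """More seeds requested than vertices available in a region."""


class MetricError(FoliakitError):
    """A similarity metric is undefined for the given inputs."""


class GridError(FoliakitError):
    """Two volumes do not share a compatible grid."""


class DomainError(FoliakitError):
    """Too many points fall outside the domain of a displacement field."""


class UndefinedDistanceError(FoliakitError):
    """A distance is undefined because one of the point sets is empty."""


class PhantomSpecError(FoliakitError):
    """A synthetic phantom specification is invalid or self-intersecting."""


class FoliakitWarning(UserWarning):
    """Base class for all foliakit warnings."""


class ResolutionWarning(FoliakitWarning):
    """Voxel size too coarse to keep distinct structures separable."""


class ExtrapolationWarning(FoliakitWarning):
    """Points outside a field/grid domain were extrapolated."""


class FragmentationWarning(FoliakitWarning):
    """A patch or region was fragmented and had to be repaired."""
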