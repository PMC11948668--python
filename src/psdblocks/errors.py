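"""Exception hierarchy for the psdblocks pipeline.

All pipeline-specific failures derive from :class:`PsdBlocksError` so callers
(and the CLI) can distinguish domain errors from programming errors.
"""


class PsdBlocksError(Exception):
    """Base class for all psdblocks errors."""


class MrcFormatError(PsdBlocksError):
    """Malformed or unsupported MRC file header/payload."""


class UnsupportedVolumeError(PsdBlocksError):
    """Valid file, but a volume the pipeline does not handle (e.g. anisotropic voxels)."""


class SchemaError(PsdBlocksError):
    """Annotation table or ground-truth JSON violates the documented schema."""


class InsufficientMembraneError(PsdBlocksError):
    """Fewer than three non-collinear membrane points; plane is underdetermined."""


class PlacementError(PsdBlocksError):
    """Synthetic layout generation could not place all requested blocks."""

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"could not place {requested} blocks (placed {achieved}) "
            f"within the rejection-sampling budget"
        )


class EmptySlabError(PsdBlocksError):
    """The requested slab does not intersect the volume."""


class BoundsError(PsdBlocksError):
    """A requested region lies outside the data."""


class DegenerateBlockError(PsdBlocksError):
    """A nanoblock with D = 0 (single pixel) cannot enter ratio analyses."""


class FitFailureError(PsdBlocksError):
    """Peak fitting failed to converge; carries the best attempt."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class ConfigError(PsdBlocksError):
    """Invalid or unknown configuration key/value."""


class InputError(PsdBlocksError):
    """Invalid statistical input (e.g. empty sample)."""
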