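"""Exception hierarchy shared across the pipeline."""


class TrendkitError(Exception):
    """Base class for all fatal pipeline errors."""


class InputError(TrendkitError):
    """Unreadable, malformed, or inconsistent input data."""


class GridMismatchError(InputError):
    """A mask grid does not match its companion CT grid. Grids are never resampled."""


class GeometryError(TrendkitError):
    """Degenerate voxel-to-world transform (singular linear part)."""


class EmptyMaskError(TrendkitError):
    """Raised when HU statistics are requested for a mask with no voxels.

    Callers treat this as "structure absent": no feature records are emitted,
    which in turn triggers the pairwise-existence exclusion downstream.
    """


class PhantomError(TrendkitError):
    """Invalid synthetic phantom specification."""
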