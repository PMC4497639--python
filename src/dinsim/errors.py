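"""Exception types raised across the simulator."""


class DinsimError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(DinsimError, ValueError):
    """A stimulus, afferent or DIN parameter is outside its valid domain."""


class GridMismatchError(DinsimError, ValueError):
    """Two traces that must share a sampling grid do not."""


class SegmentationError(DinsimError, ValueError):
    """A joint-angle trace could not be segmented into ramps and holds."""


class DegenerateSpaceError(DinsimError, ValueError):
    """The selectivity matrix does not span a usable coding-space."""


class ThresholdError(DinsimError, ValueError):
    """Linear separator thresholds are missing or cannot be fitted."""
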