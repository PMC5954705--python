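"""Exception types shared across the package."""


class ThyrotexError(Exception):
    """Base class for package-specific failures."""


class FormatError(ThyrotexError, ValueError):
    """A volume file or array does not satisfy the expected format."""


class SegmentationError(ThyrotexError, ValueError):
    """Lesion segmentation cannot produce a region of interest."""


class SizingError(ThyrotexError, ValueError):
    """A phantom nodule does not fit inside its grid."""


class ParameterError(ThyrotexError, ValueError):
    """Invalid specification or configuration parameters."""
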