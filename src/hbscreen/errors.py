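"""Exception hierarchy for the screening pipeline.

Every stage raises a subclass of :class:`HbscreenError`, so callers can
catch pipeline failures without masking programming errors.
"""


class HbscreenError(Exception):
    """Base class for all errors raised by hbscreen."""


class InvalidSpecError(HbscreenError, ValueError):
    """A simulation or run specification violates its invariants."""


class FormatError(HbscreenError, ValueError):
    """An image or manifest does not have the expected layout."""


class ParameterError(HbscreenError, ValueError):
    """An operation received an out-of-contract parameter."""


class DegenerateImageError(HbscreenError, ValueError):
    """The image histogram cannot support the requested operation
    (e.g. Otsu thresholding of a constant image)."""


class NoLanesError(HbscreenError, RuntimeError):
    """Lane detection found no usable foreground components."""


class GeometryError(HbscreenError, ValueError):
    """A box or map does not fit the image it refers to."""


class ClockError(HbscreenError, ValueError):
    """A timing record has a negative span."""


class IOFailure(HbscreenError, OSError):
    """A file could not be read or written; the message names the path."""
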