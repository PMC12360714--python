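"""Exception hierarchy for phantomqa."""


class PhantomQAError(Exception):
    """Base class for all phantomqa errors."""


class InvalidConfigError(PhantomQAError, ValueError):
    """A scene or analysis configuration violates its invariants."""


class DegenerateSceneError(PhantomQAError, ValueError):
    """A scene cannot be rendered (e.g. no well fits inside the frame)."""


class ImageFormatError(PhantomQAError, ValueError):
    """An input image is not reducible to a single grayscale channel."""


class FrameMismatchError(PhantomQAError, ValueError):
    """Images or maps that must share pixel dimensions do not."""


class FitError(PhantomQAError, RuntimeError):
    """A surface or regression fit could not be performed."""


class InsufficientCenterError(PhantomQAError, ValueError):
    """Too few wells near the image center to build a reference grid."""


class OutOfBoundsError(PhantomQAError, ValueError):
    """A region of interest extends beyond the image frame."""
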