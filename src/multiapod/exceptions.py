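"""Exception hierarchy.

Every error raised by this package derives from :class:`MultiapodError`, so
callers (and the CLI) can catch one base class and still see which processing
stage failed from the concrete subclass.
"""


class MultiapodError(Exception):
    """Base class for all errors raised by multiapod."""


class InvalidWindowError(MultiapodError, ValueError):
    """Bad window length or control parameter."""


class ResolutionError(MultiapodError, ValueError):
    """Spectrum sampled too coarsely for the requested measurement."""


class NoCrossingError(MultiapodError, ValueError):
    """A level-crossing width was requested at a level the curve never reaches."""


class AxisMismatchError(MultiapodError, ValueError):
    """Spectra to be combined do not share a bin axis."""


class GridMismatchError(MultiapodError, ValueError):
    """Images to be combined do not share a pixel grid."""


class NormalizationError(MultiapodError, ValueError):
    """An image expected to be self-normalized is not."""


class StageOrderError(MultiapodError, ValueError):
    """A pipeline stage was applied to an image in the wrong state."""


class GeometryError(MultiapodError, ValueError):
    """Phantom or array geometry is physically invalid."""


class PhantomError(MultiapodError, ValueError):
    """Empty or otherwise unusable phantom specification."""


class ApodizationMappingError(MultiapodError, ValueError):
    """Apodization profile cannot be mapped onto the active subaperture."""


class RoiError(MultiapodError, ValueError):
    """Region of interest empty or outside the image."""
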