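"""Exception types raised across the package."""


class VineleafError(Exception):
    """Base class for package errors."""


class EmptyMaskError(VineleafError, ValueError):
    """A binary mask contains no foreground pixels."""


class ContourExtractionError(VineleafError, RuntimeError):
    """No closed iso-contour could be extracted from a mask."""


class DegenerateContourError(VineleafError, ValueError):
    """A contour collapses to a point or a line and cannot be processed."""


class ParameterError(VineleafError, ValueError):
    """A configuration or generator parameter is outside its legal range."""


class DataError(VineleafError, ValueError):
    """Input data violate a structural contract (non-finite values, bad joins...)."""
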