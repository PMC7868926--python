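"""Exception types shared across the package."""


class BiofilmscapeError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BiofilmscapeError):
    """Input data violates a documented invariant."""


class GeometryError(BiofilmscapeError):
    """Raster/region geometry mismatch or out-of-bounds request."""


class RangeError(BiofilmscapeError):
    """Requested coordinate lies outside a tabulated range."""


class FitError(BiofilmscapeError):
    """A statistical fit cannot be carried out on the given data."""
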