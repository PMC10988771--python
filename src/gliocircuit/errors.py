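"""Exception hierarchy shared across the pipeline."""


class GliocircuitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GliocircuitError, ValueError):
    """A file or table does not conform to the expected format."""


class RangeError(GliocircuitError, ValueError):
    """A value (marker, mask, coordinate) lies outside the valid range."""


class ShapeError(GliocircuitError, ValueError):
    """An array has the wrong dimensionality or incompatible shape."""


class DegenerateInputError(GliocircuitError, ValueError):
    """The input is formally valid but degenerate for the requested operation."""
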