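"""Exception types shared across the package."""


class PanoViewError(Exception):
    """Base class for all panoview errors."""


class MatrixFormatError(PanoViewError, ValueError):
    """An input file could not be parsed as an expression matrix."""


class MatrixValidationError(PanoViewError, ValueError):
    """Parsed data violate an ExpressionMatrix invariant."""


class DegenerateInputError(PanoViewError, ValueError):
    """Geometry or matrix shape too degenerate for the requested operation."""


class UndefinedDistanceError(PanoViewError, ValueError):
    """Correlation distance is undefined (a constant expression vector)."""
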