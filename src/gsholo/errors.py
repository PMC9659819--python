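"""Exception and warning types shared across the package."""


class GsholoError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(GsholoError, ValueError):
    """Propagation geometry is unphysical (non-positive pitch, tiny grid, ...)."""


class InvalidConfigError(GsholoError, ValueError):
    """A retrieval or phantom configuration violates its invariants."""


class ShapeError(GsholoError, ValueError):
    """Array arguments have mismatched or unusable shapes."""


class InvalidRangeError(GsholoError, ValueError):
    """A value range is degenerate or the data falls outside the declared range."""


class InvalidInputError(GsholoError, ValueError):
    """Input data violates a precondition (empty, negative where forbidden, ...)."""


class UndefinedCorrelationError(GsholoError, ValueError):
    """Correlation requested against a zero-energy field."""


class FormatError(GsholoError, ValueError):
    """An image does not have the expected channel layout."""


class PlacementError(GsholoError, RuntimeError):
    """Phantom objects could not be placed on the canvas without overlap."""


class IntegrityError(GsholoError, RuntimeError):
    """A run manifest references outputs that are missing or inconsistent."""


class DegenerateInputWarning(UserWarning):
    """Constant-valued input to a min-max normalisation; all-zeros returned."""
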