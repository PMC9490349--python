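"""Exception hierarchy shared by all percwear modules."""


class PercwearError(Exception):
    """Base class for all percwear errors."""


class MalformedInputError(PercwearError):
    """A file or table could not be parsed into the expected structure."""


class DegeneracyError(PercwearError):
    """Geometry is degenerate (collinear/coplanar points, zero area...)."""


class PairingError(PercwearError):
    """Two objects that must derive from the same model do not match."""


class ParameterError(PercwearError):
    """An invalid parameter value (non-positive radius, bad distribution...)."""


class InsufficientSupportError(PercwearError):
    """Too few points to fit a local plane / define a local statistic."""


class SchemaError(PercwearError):
    """A required column is missing from an input table."""
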