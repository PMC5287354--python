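"""Exception types shared across the package."""


class SubtomoError(Exception):
    """Base class for all package errors."""


class FormatError(SubtomoError):
    """A file is malformed or of the wrong kind."""


class ShapeError(SubtomoError):
    """Array dimensionality or sizes are inconsistent."""


class SchemaError(SubtomoError):
    """A tabular file is missing required columns."""


class ValidationError(SubtomoError):
    """A value violates a domain invariant (e.g. ccc outside [-1, 1])."""


class ParameterError(SubtomoError):
    """An argument is outside its documented domain."""


class GeometryError(SubtomoError):
    """An object does not fit the requested box or volume."""


class DependencyError(SubtomoError):
    """A pipeline stage refers to an upstream output that does not exist."""
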