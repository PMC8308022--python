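"""Exception hierarchy shared across the package."""


class MirrorFaceError(Exception):
    """Base class for all package errors."""


class SchemaMismatchError(MirrorFaceError):
    """A landmark file or record does not match the declared schema."""


class LandmarkParseError(MirrorFaceError):
    """A landmark file could not be parsed (bad format, non-numeric values)."""


class DegenerateGeometryError(MirrorFaceError):
    """The point configuration does not admit the requested construction."""


class InsufficientConstraintsError(MirrorFaceError):
    """Too few usable points to estimate a symmetry axis."""


class AxisOutOfFrameError(MirrorFaceError):
    """The symmetry axis does not intersect the image."""


class ParameterError(MirrorFaceError):
    """An argument is outside its documented domain."""


class ProviderError(MirrorFaceError):
    """A landmark detector plug-in is missing or misconfigured."""
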