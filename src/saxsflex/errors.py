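"""Exception hierarchy for saxsflex."""


class SaxsflexError(Exception):
    """Base class for all saxsflex errors."""


class TopologyError(SaxsflexError):
    """Invalid segment topology (overlap, gap, missing template, ...)."""


class GeometryError(SaxsflexError):
    """Geometrically impossible construction request."""


class ClashError(SaxsflexError):
    """Conformer sampling exhausted its retry budget due to steric clashes."""


class CurveError(SaxsflexError):
    """Invalid scattering curve or curve operation."""


class GridMismatchError(CurveError):
    """Two curves do not share a common q grid."""


class FitError(SaxsflexError):
    """Fitting preconditions violated (missing sigma, bad data, ...)."""
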