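"""Exception hierarchy for octlayers.

All package errors derive from :class:`OctLayersError` so callers can catch
one base class; most also derive from the matching builtin (``ValueError`` /
``RuntimeError``) so untyped call sites behave sensibly.
"""


class OctLayersError(Exception):
    """Base class for all octlayers errors."""


class InvalidParameterError(OctLayersError, ValueError):
    """A parameter is outside its documented domain."""


class InvalidGeometryError(OctLayersError, ValueError):
    """Phantom geometry would cross boundaries or leave the image."""


class InvalidInputError(OctLayersError, ValueError):
    """Input data violates a precondition (NaN, wrong shape, ...)."""


class InfeasibleBandError(OctLayersError, RuntimeError):
    """No path satisfying the connectivity constraint exists in the band."""


class SearchSpaceError(OctLayersError, ValueError):
    """Exhaustive enumeration refused: search space too large."""


class DetectionFailureError(OctLayersError, RuntimeError):
    """A boundary initialization stage found no usable candidate."""


class InvalidAnchorError(OctLayersError, ValueError):
    """A correction anchor lies outside the enclosing boundaries."""


class IncompleteDesignError(OctLayersError, ValueError):
    """A measurement table is missing cells required by the study design."""


class SampleSizeError(OctLayersError, ValueError):
    """Too few subjects/ratings for the requested statistic."""


class DegenerateTestError(OctLayersError, ValueError):
    """A test statistic is undefined (e.g. zero-variance differences)."""


class CorruptFileError(OctLayersError, ValueError):
    """A file on disk violates an invariant it should carry."""


class UnsupportedFormatError(OctLayersError, ValueError):
    """Unsupported image/file format."""


class ConfigError(OctLayersError, ValueError):
    """Malformed or incomplete configuration."""
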