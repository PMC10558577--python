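"""Exception hierarchy for implantsize.

All package-specific errors derive from :class:`ImplantSizeError` so callers
can catch everything with one clause while the CLI maps subtypes onto exit
codes (config/usage problems vs. runtime failures).
"""


class ImplantSizeError(Exception):
    """Base class for all implantsize errors."""


class AnnotationFormatError(ImplantSizeError):
    """Annotation file is missing the expected polygon structure."""


class VertexCountError(AnnotationFormatError):
    """Polygon does not have exactly three vertices."""


class CollinearPointsError(ImplantSizeError):
    """The three key points are (numerically) collinear."""


class DegenerateSegmentError(ImplantSizeError):
    """Two points expected to span a segment coincide."""


class AnisotropicSpacingError(ImplantSizeError):
    """Row and column pixel spacing differ beyond tolerance."""


class ConfigurationError(ImplantSizeError):
    """A required configuration value is missing or invalid."""


class InsufficientDataError(ImplantSizeError):
    """Not enough records/points for the requested operation."""


class CardinalityError(ImplantSizeError):
    """Mismatched counts (labels vs clusters, sequence lengths ...)."""


class ModelStateError(ImplantSizeError):
    """Operation requires model state that has not been established."""
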