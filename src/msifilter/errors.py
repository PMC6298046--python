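"""Exception hierarchy shared across the package."""


class MSIFilterError(Exception):
    """Base class for all package-specific errors."""


class DegenerateImageError(MSIFilterError):
    """An image is constant (or has no signal) where a non-trivial one is required."""


class UndefinedScoreError(MSIFilterError):
    """A similarity/regularity score is undefined for the given input.

    Callers decide policy; the filters treat an undefined similarity as a
    failing score (``-inf`` sentinel).
    """


class DimensionMismatchError(MSIFilterError):
    """Two images/masks that must share a grid shape do not."""


class ConfigError(MSIFilterError):
    """Invalid pipeline configuration."""
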