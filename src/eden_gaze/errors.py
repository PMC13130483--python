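"""Exception types shared across the package."""


class EdenGazeError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(EdenGazeError):
    """A screen/stimulus geometry field is nonpositive or degenerate."""


class InvalidConfigError(EdenGazeError):
    """A configuration value violates its contract."""


class InsufficientDataError(EdenGazeError):
    """Not enough valid samples to estimate the requested model."""


class InvalidDistributionError(EdenGazeError):
    """A vector expected to lie on the probability simplex does not."""


class GroupingError(EdenGazeError):
    """Too few participants (or degenerate ratings) to form groups."""


class PipelineDependencyError(EdenGazeError):
    """A pipeline stage was requested without its upstream outputs."""
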