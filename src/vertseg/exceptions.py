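"""Exception hierarchy for the segmentation pipeline.

Each pipeline stage raises a distinct error type so callers (and the CLI,
which maps them to exit codes) can tell an initialization failure from a
contour collapse during evolution.
"""


class VertsegError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(VertsegError):
    """Input image/parameters violate a precondition (non-finite pixels, bad shape...)."""


class ConfigError(VertsegError):
    """Configuration file is malformed, has unknown keys, or a wrong schema version."""


class InitializationError(VertsegError):
    """The automatic initialization stage failed (degenerate mixture, empty mask...)."""


class ContourCollapseError(VertsegError):
    """The zero level set vanished during evolution (one sign of phi was lost)."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


class MetricError(VertsegError):
    """An evaluation metric is undefined for the given masks (e.g. empty ground truth)."""
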