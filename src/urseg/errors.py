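"""Exception hierarchy for the segmentation pipeline.

Stage-specific errors let callers (and the CLI exit codes) distinguish a
degenerate input from a seed-detection failure from a tracing failure.
"""


class URSegError(Exception):
    """Base class for all pipeline errors."""


class DegenerateInputError(URSegError):
    """The input image is unusable (too small, empty mask, ...)."""


class SeedDetectionError(URSegError):
    """Seed points or the distal-end column could not be located.

    Carries an optional ``profile`` attribute with the 1-D profile that
    failed, for diagnostics.
    """

    def __init__(self, message, profile=None, peaks=None):
        super().__init__(message)
        self.profile = profile
        self.peaks = peaks


class TracingError(URSegError):
    """Minimum-cost path tracing failed (e.g. unreachable anchor point)."""


class ContourAssemblyError(URSegError):
    """Traced paths cannot be merged into a simple closed contour."""

    def __init__(self, message, location=None):
        super().__init__(message)
        self.location = location


class StageError(URSegError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage, original):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original
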