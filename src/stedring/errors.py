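"""Typed exceptions used across the pipeline.

Every error raised by stedring derives from :class:`StedringError`, so batch
drivers can distinguish per-ring analysis failures (caught and recorded with a
failure code) from programming errors (propagated).
"""


class StedringError(Exception):
    """Base class for all stedring errors."""


class ValidationError(StedringError, ValueError):
    """Invalid configuration value or malformed argument."""


class PlacementError(StedringError):
    """Synthetic scene generation could not place a ring after bounded retries."""


class BoundsError(StedringError):
    """A requested sampling region extends beyond the image raster."""


class NoSignalError(StedringError):
    """No usable fluorescence signal at the seeded position."""


class DegenerateGeometryError(StedringError):
    """Too few or collinear points; no unique circle exists."""


class DegenerateDataError(StedringError):
    """Statistical input with no variance where variance is required."""


class CongruenceError(StedringError):
    """Channel rasters disagree in shape or pixel size."""


class FormatError(StedringError):
    """An input file is missing, malformed, or of an unsupported layout."""
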