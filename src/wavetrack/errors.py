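"""Exception types shared across the pipeline.

Every error that names a stage, a field, or a coordinate derives from
:class:`WavetrackError` so callers can catch the package's failures as a family.
"""


class WavetrackError(Exception):
    """Base class for all wavetrack errors."""


class ValidationError(WavetrackError, ValueError):
    """A parameter or input failed validation; the message names the field."""


class GeometryError(WavetrackError, ValueError):
    """A geometric precondition failed (path outside image, overlapping ROIs...)."""


class SeedError(WavetrackError, ValueError):
    """A seed point does not lie on foreground; the message names the coordinate."""


class DisconnectionError(WavetrackError, ValueError):
    """Two points lie in different connected components of the feature map."""


class InsufficientDataError(WavetrackError, ValueError):
    """Too few samples for the requested statistic."""


class NormalizationError(WavetrackError, ValueError):
    """A normalization denominator is degenerate (e.g. zero actin mean)."""


class CoverageError(WavetrackError, ValueError):
    """Aligned traces share no common support."""
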