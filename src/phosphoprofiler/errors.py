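"""Exception hierarchy for the phosphoprofiler pipeline.

All errors derive from :class:`PhosphoProfilerError` so callers can catch the
package's failures with a single except clause while the CLI maps them to
clean non-zero exits.
"""


class PhosphoProfilerError(Exception):
    """Base class for all phosphoprofiler errors."""


class LayoutError(PhosphoProfilerError):
    """A membrane layout violates its structural invariants."""


class RegistrationError(PhosphoProfilerError):
    """A layout cannot be mapped onto an image without losing spots."""


class MeasurementError(PhosphoProfilerError):
    """A spot cannot be measured (e.g. disc out of image bounds)."""


class BackgroundError(PhosphoProfilerError):
    """Background estimation failed (e.g. no negative-control spots)."""


class SaturationError(PhosphoProfilerError):
    """Rendered intensities exceed the bit depth and clipping is disabled."""


class ConfigError(PhosphoProfilerError):
    """A simulation or analysis configuration is invalid."""


class NormalizationError(PhosphoProfilerError):
    """A profile cannot be normalized (e.g. zero reference signal)."""


class DegenerateProfileError(PhosphoProfilerError):
    """A profile is degenerate for the requested view (e.g. all zero)."""


class InsufficientDataError(PhosphoProfilerError):
    """Too few usable values for the requested statistic."""


class SchemeError(PhosphoProfilerError):
    """An activation-calling scheme's prerequisites are unmet."""


class PairingError(PhosphoProfilerError):
    """Array and IHC samples cannot be paired one-to-one."""


class ComparisonError(PhosphoProfilerError):
    """Serial profiles are not comparable (e.g. mixed array types)."""


class DataError(PhosphoProfilerError):
    """A cohort matrix violates its contract (negatives, missing cells)."""


class DistanceError(PhosphoProfilerError):
    """A distance is undefined (e.g. zero-variance vector)."""


class ClusterError(PhosphoProfilerError):
    """Hierarchical clustering cannot proceed on the given matrix."""
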