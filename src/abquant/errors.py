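"""Exception hierarchy for the pipeline.

All configuration and data errors derive from :class:`AbquantError` so callers
can catch pipeline problems without swallowing programming errors.
"""


class AbquantError(Exception):
    """Base class for all pipeline errors."""


class InvalidConfigError(AbquantError, ValueError):
    """A simulation or analysis configuration violates its invariants."""


class NormalizationError(AbquantError, ValueError):
    """df/f normalization is undefined (e.g. non-positive f0)."""


class FilterParameterError(AbquantError, ValueError):
    """Low-pass cutoff incompatible with the sampling rate."""


class DetectionError(AbquantError, ValueError):
    """Transient detection cannot proceed (e.g. zero noise floor)."""


class WindowError(AbquantError, ValueError):
    """An integration or quiet window does not fit inside the trace."""


class InsufficientDataError(AbquantError, ValueError):
    """Too few observations for the requested statistic."""


class IdentifiabilityError(AbquantError, ValueError):
    """Model parameters are not identifiable from the supplied data."""


class FitConvergenceError(AbquantError, RuntimeError):
    """Non-linear regression failed to converge."""
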