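"""Exception types shared across the pipeline.

The CLI maps :class:`ConfigError` to exit code 2 and :class:`DataError`
to exit code 3; everything else is a programming error and propagates.
"""


class RedSnowError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(RedSnowError, ValueError):
    """An argument violates a precondition (bad threshold, fraction sum, ...)."""


class ConfigError(RedSnowError, ValueError):
    """The run configuration is invalid or incomplete."""


class DataError(RedSnowError, ValueError):
    """Input data violates a contract (zero-depth sample, missing label, ...)."""


class DimensionError(RedSnowError, ValueError):
    """Grids or matrices have incompatible shapes."""


class UnitsError(RedSnowError, ValueError):
    """An operation was applied to data in the wrong units (DN vs reflectance)."""
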