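"""Typed exceptions shared across the pipeline.

Exit-code mapping used by the CLI: validation/configuration problems -> 1,
I/O problems -> 2.
"""


class FieldscaleError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FieldscaleError):
    """A configuration value is missing, unknown, or out of range."""


class ValidationError(FieldscaleError):
    """An input violates a documented precondition."""


class DegenerateInputError(ValidationError):
    """Input is technically well-formed but statistically degenerate
    (e.g. all pixels identical, coincident CWSI baselines)."""


class RasterIOError(FieldscaleError):
    """A raster or image file could not be read/written as expected."""
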