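"""Exception hierarchy shared across the package."""


class MirEqtlError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MirEqtlError, ValueError):
    """Invalid simulation or pipeline configuration."""


class InputError(MirEqtlError, ValueError):
    """Malformed or degenerate input data."""


class NormalizationError(MirEqtlError, RuntimeError):
    """A microarray cannot be normalized (e.g. a control probe is not effective)."""


class DegenerateModelError(MirEqtlError, RuntimeError):
    """A model fit or evaluation is degenerate (no events, constant index, ...)."""
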