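"""Exception hierarchy for the ffoafuse package."""


class FusionError(Exception):
    """Base class for all ffoafuse errors."""


class ConfigurationError(FusionError, ValueError):
    """An unknown filter name, invalid parameter value, or malformed config."""


class ValidationError(FusionError, ValueError):
    """Input data violates a documented precondition (non-finite, wrong range...)."""


class DimensionError(ValidationError):
    """Array shapes are inconsistent or too small for the requested operation."""
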