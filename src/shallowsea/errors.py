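"""Exception hierarchy shared across the package."""


class ShallowSeaError(Exception):
    """Base class for all package errors."""


class ValidationError(ShallowSeaError):
    """Input values violate a physical or structural precondition."""


class ConfigurationError(ShallowSeaError):
    """Mismatched shapes/band counts or malformed configuration."""


class CoverageError(ShallowSeaError):
    """A band's spectral support is not covered by the supplied grid."""
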