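"""Exception types shared across the package."""


class MsptirrError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MsptirrError, ValueError):
    """A parameter is outside its valid domain."""


class InvalidInputError(MsptirrError, ValueError):
    """Input data are malformed (non-finite values, ragged channels, ...)."""


class InsufficientDataError(MsptirrError, ValueError):
    """A series is too short for the requested operation."""
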