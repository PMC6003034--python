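"""Exception hierarchy shared across the package."""


class ArganetError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(ArganetError, ValueError):
    """Raised when input data violate a precondition (negative areas, absorbances...)."""


class ValidationError(ArganetError, ValueError):
    """Raised when a fatty-acid profile fails range or closure validation."""


class UndefinedRatioError(ArganetError, ZeroDivisionError):
    """Raised when a ratio has a zero denominator (e.g. total SFA = 0)."""


class EncodingError(ArganetError, KeyError):
    """Raised when a categorical label is missing from its coding map."""


class InsufficientDataError(ArganetError, ValueError):
    """Raised when fewer samples are available than a statistic requires."""


class ConfigurationError(ArganetError, ValueError):
    """Raised for invalid configuration (bad thresholds, overlapping grade bands...)."""
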