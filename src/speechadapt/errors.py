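"""Exception hierarchy shared across the package.

Exit-code mapping used by the command-line interface:
``ConfigurationError`` -> 2, ``SupportError`` -> 3.
"""


class SpeechAdaptError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SpeechAdaptError):
    """Invalid parameter, scenario field, or model construction request."""


class MonotonicityError(ConfigurationError):
    """A sensorimotor mapping would not be strictly increasing."""


class SupportError(SpeechAdaptError):
    """Numerical support too narrow: posterior mass leaks off the grid."""


class BoundaryNotFoundError(SpeechAdaptError):
    """A categorization curve has no 0.5 crossing within the grid."""
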