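"""Exception hierarchy shared across the package.

``ConfigurationError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class LinesenseError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(LinesenseError):
    """Invalid configuration (bad dimensions, variances, thresholds...)."""


class DataError(LinesenseError):
    """Input data cannot support the requested computation."""


class UndefinedPanelResponseError(DataError):
    """Panel-average treatment response is (numerically) zero, so the
    sensitivity index denominator is undefined."""
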