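"""Exception hierarchy shared across the package.

``ConfigError`` covers invalid user-supplied parameters, ``DataError``
covers malformed or inconsistent input data; the command-line layer maps
them to distinct exit codes (2 and 3).
"""


class SwagnetError(Exception):
    """Base class for package errors."""


class ConfigError(SwagnetError):
    """Invalid configuration or parameter combination."""


class DataError(SwagnetError):
    """Malformed, inconsistent or degenerate input data."""
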