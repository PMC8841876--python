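"""Exception hierarchy.

ConfigError maps to CLI exit code 2, DataError to exit code 3.
"""


class FamscanError(Exception):
    """Base class for all package errors."""


class ConfigError(FamscanError):
    """Invalid configuration (bad parameter values, degenerate models)."""


class DataError(FamscanError):
    """Malformed or inconsistent input data (parse errors, bad annotations)."""
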