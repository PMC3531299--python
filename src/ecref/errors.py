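"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError (and
subclasses) -> 3.
"""


class EcrefError(Exception):
    """Base class for all package errors."""


class ConfigError(EcrefError):
    """Invalid configuration, thresholds or simulation parameters."""


class DataError(EcrefError):
    """Input data violates an integrity constraint or a precondition."""


class FormatError(DataError):
    """A file does not conform to the expected tabular layout."""
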