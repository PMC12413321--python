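"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3.
"""


class TransportNLPError(Exception):
    """Base class for all package errors."""


class ConfigError(TransportNLPError):
    """A configuration file or parameter set is malformed."""


class PatternError(ConfigError):
    """A lexicon or template regular expression failed to compile."""

    def __init__(self, label: str, pattern: str, reason: str):
        self.label = label
        self.pattern = pattern
        super().__init__(f"pattern {label!r} ({pattern!r}) is invalid: {reason}")


class DataError(TransportNLPError):
    """Input data violate a contract (missing ids, unknown patients, ...)."""
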