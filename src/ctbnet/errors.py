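"""Exception hierarchy shared across the pipeline.

Exit-code mapping for the CLI: ConfigError -> 2, DataError -> 3.
"""


class CtbnetError(Exception):
    """Base class for all package errors."""


class ConfigError(CtbnetError):
    """Invalid configuration (bad value, unknown key, unparseable file)."""

    def __init__(self, errors):
        if isinstance(errors, str):
            errors = [errors]
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class DataError(CtbnetError):
    """Invalid or degenerate data (empty selection, misaligned tables, ...)."""
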