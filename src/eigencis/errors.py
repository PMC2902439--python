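"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataContractError -> 3,
NumericalError -> 4.
"""


class EigencisError(Exception):
    """Base class for package errors."""


class ConfigError(EigencisError):
    """Invalid configuration (bad parameter values, missing inputs)."""


class DataContractError(EigencisError):
    """Input tables violate a schema or cross-table consistency contract."""


class NumericalError(EigencisError):
    """A numerical procedure failed (rank deficiency, non-finite input)."""
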