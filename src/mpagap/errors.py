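"""Exception hierarchy shared by the pipeline and the CLI.

The CLI maps these to exit codes: ConfigError → 2, DataError → 3,
InvariantError → 4.
"""


class MpaGapError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(MpaGapError):
    """Invalid configuration or parameters."""

    exit_code = 2


class DataError(MpaGapError):
    """Malformed, inconsistent, or out-of-contract input data."""

    exit_code = 3


class InvariantError(MpaGapError):
    """An internal consistency check failed."""

    exit_code = 4
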