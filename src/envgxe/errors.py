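"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: InvalidConfigError -> 2, DataError -> 3.
"""


class EnvGxeError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(EnvGxeError):
    """A configuration value violates its documented constraints."""


class DataError(EnvGxeError):
    """Input data are malformed, degenerate or insufficient for the analysis."""
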