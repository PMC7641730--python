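"""Exception hierarchy.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
FitConvergenceError -> 4 (only when fatal non-convergence is requested).
"""


class NmrbindError(Exception):
    """Base class for all package errors."""


class ConfigError(NmrbindError):
    """Invalid or inconsistent configuration."""


class DataError(NmrbindError):
    """Malformed, missing or internally inconsistent input data."""


class FitConvergenceError(NmrbindError):
    """A fit failed to converge and the caller asked for that to be fatal."""
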