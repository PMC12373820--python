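"""Exception hierarchy.

Exit-code mapping used by the CLI: configuration errors -> 2, data errors -> 3,
numerical/statistical errors -> 4.
"""


class CtdoseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CtdoseError):
    """An invalid configuration value; the message names the offending field."""


class DataError(CtdoseError):
    """Malformed or inconsistent input tables (orphan rows, missing columns)."""


class NumericalError(CtdoseError):
    """Degenerate statistical input (zero variance, rank deficiency, separation)."""
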