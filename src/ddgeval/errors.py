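"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes (config -> 2, data -> 3,
undefined stratum -> 4), so downstream code should raise the most
specific class that applies.
"""


class DdgEvalError(Exception):
    """Base class for all package errors."""


class ConfigError(DdgEvalError):
    """Invalid run configuration or invalid operation parameters."""


class DataError(DdgEvalError):
    """Malformed or inconsistent input data (duplicate ids, bad labels, ...)."""


class UndefinedStratumError(DdgEvalError):
    """A stratum has no usable records in one of the two classes.

    Signals the 'undefined stratum' condition: the requested quantity
    (AUC, precision) does not exist for this subset of the data.
    """
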