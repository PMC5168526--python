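"""Exception hierarchy shared across the pipeline."""


class VaxsentError(Exception):
    """Base class for all package errors."""


class ConfigError(VaxsentError):
    """Invalid parameters or pipeline configuration."""


class DataError(VaxsentError):
    """Malformed or inconsistent input data."""


class UndefinedStatisticError(VaxsentError):
    """A statistic is undefined for the given input (e.g. single-class AUC,
    zero expected disagreement, all-identical values in a median test)."""
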