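"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
ConvergenceError -> 4 (outputs are still written in that case).
"""


class GmmfusionError(Exception):
    """Base class for all package errors."""


class ConfigError(GmmfusionError):
    """Invalid run configuration or parameter value."""


class DataError(GmmfusionError):
    """Invalid input data: missing files, bad labels, non-finite pixels."""


class ConvergenceError(GmmfusionError):
    """A solver stopped at max_sweeps without reaching its tolerance."""
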