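"""Exception hierarchy.

``InputError`` covers malformed or inconsistent user input (CLI exit
code 2); ``DegenerateDataError`` covers statistically degenerate data
such as zero-variance paired differences (CLI exit code 3).
"""


class PAHFateError(Exception):
    """Base class for all package errors."""


class InputError(PAHFateError, ValueError):
    """Malformed, missing or inconsistent input data."""


class InvalidStructureError(InputError):
    """A compound that cannot be a PAH (fewer than two fused rings)."""


class MissingBenchmarkError(InputError):
    """The benchmark compound is absent, unquantified or zero in a bottle."""


class BelowLOQError(InputError):
    """A computation requested on a measurement below the limit of quantification."""


class DegenerateDataError(PAHFateError):
    """Statistic undefined for the data (e.g. zero variance of paired differences)."""
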