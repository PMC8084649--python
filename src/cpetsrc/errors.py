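"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes (input/schema errors -> 2,
configuration errors -> 3).
"""


class CpetSrcError(Exception):
    """Base class for all package errors."""


class InputError(CpetSrcError, ValueError):
    """Invalid data passed to an operation (wrong shape, non-finite, empty...)."""


class ConfigurationError(CpetSrcError, ValueError):
    """Invalid configuration or hyperparameter combination."""


class FormatError(InputError):
    """Malformed file content (ragged rows, missing columns...)."""


class DegenerateCohortError(InputError):
    """Cohort statistics are undefined (e.g. zero spread in change rates)."""
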