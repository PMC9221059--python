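"""Exception hierarchy shared across the pipeline."""


class ProcoexError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(ProcoexError):
    """An invalid configuration value; the message names the offending field."""


class FormatError(ProcoexError):
    """A malformed input file (matrix, GMT, chromosome map, edge list)."""


class InputError(ProcoexError):
    """A precondition violation on otherwise well-formed data."""


class CalibrationError(ProcoexError):
    """The permutation null could not be fit (e.g. non-negative tail slope)."""
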