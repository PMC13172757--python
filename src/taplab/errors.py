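"""Exception hierarchy shared across the pipeline stages."""


class TaplabError(Exception):
    """Base class for all taplab errors."""


class InvalidArgumentError(TaplabError, ValueError):
    """A parameter or input violates a documented precondition."""


class FormatError(TaplabError, ValueError):
    """An input file does not conform to the expected dialect."""


class InsufficientCyclesError(TaplabError):
    """Fewer tap cycles were detected than the features require."""


class UndefinedStatisticError(TaplabError):
    """A statistic is undefined for the given input (e.g. constant sample)."""
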