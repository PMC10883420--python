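"""Exception hierarchy used across the package."""


class StwmdError(Exception):
    """Base class for all package errors."""


class FormatError(StwmdError, ValueError):
    """A file does not conform to the expected dialect."""


class DuplicateCellError(FormatError):
    """The same (stage, sample, region, gene) cell appears twice."""


class DomainError(StwmdError, ValueError):
    """A value is outside its mathematical domain (negative expression, f <= 1, ...)."""


class ConfigurationError(StwmdError, ValueError):
    """A configuration or contract violation (empty stage, infeasible k, ...)."""
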