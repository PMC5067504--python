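"""Exception hierarchy for the t2di package."""


class T2diError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(T2diError, ValueError):
    """A configuration value violates its documented constraints."""


class ParseError(T2diError, ValueError):
    """A text input file is malformed; the message names the offending line."""


class DegenerateInputError(T2diError, ValueError):
    """Input is formally valid but the requested statistic is undefined on it."""


class ValidationError(T2diError, ValueError):
    """Numeric input outside its documented domain (e.g. p-value not in [0,1])."""
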