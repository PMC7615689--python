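"""Exception hierarchy for streetnav."""


class StreetNavError(Exception):
    """Base class for all streetnav errors."""


class InvalidParameterError(StreetNavError, ValueError):
    """A parameter violates its documented domain."""


class SchedulingInfeasibleError(StreetNavError, RuntimeError):
    """No street ordering satisfies the scheduling constraints."""


class NotScorableError(StreetNavError, ValueError):
    """A trajectory cannot be scored (e.g. it was aborted)."""


class UndefinedPIError(StreetNavError, ZeroDivisionError):
    """Performance index undefined (zero error or movement time)."""


class MissingAngleError(StreetNavError, KeyError):
    """A grid angle has no observations in a difficulty profile."""


class DegenerateDesignError(StreetNavError, ValueError):
    """Rank-deficient or otherwise unusable statistical design."""


class UndefinedCorrelationError(StreetNavError, ValueError):
    """Correlation undefined because one variable has zero variance."""


class NoSolutionError(StreetNavError, RuntimeError):
    """A numerical search exhausted its range without a solution."""


class ConfigError(StreetNavError, ValueError):
    """Malformed run configuration (unknown keys, bad types)."""


class ParseError(StreetNavError, ValueError):
    """Malformed input file."""
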