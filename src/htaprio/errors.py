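"""Exception hierarchy shared across the package.

Each leaf class carries the process exit code the command-line layer uses,
so library errors map onto distinct shell-visible failure classes.
"""


class HtaPrioError(Exception):
    """Base class for all htaprio errors."""

    exit_code = 1


class ParseError(HtaPrioError):
    """A file could not be read in any supported dialect."""

    exit_code = 2


class InvalidInputError(HtaPrioError):
    """Input violates a precondition (bad value, mismatched labels, ...)."""

    exit_code = 3


class ConfigurationError(HtaPrioError):
    """Configuration is incomplete for the request (e.g. panel size missing
    from the Lawshe table, or no random index for the matrix dimension)."""

    exit_code = 3


class DegenerateInputError(HtaPrioError):
    """Mathematically degenerate input: an all-zero criterion column, a zero
    weight, or identical alternatives that make relative closeness undefined."""

    exit_code = 4


class ConsistencyError(HtaPrioError):
    """Pairwise judgments exceed the acceptable inconsistency ratio (0.1) and
    weight emission was refused."""

    exit_code = 5
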