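"""Exception hierarchy.

Errors are grouped by pipeline exit code: configuration problems (exit 2),
data/format problems (exit 3) and statistical degeneracies (exit 4).
"""


class MycsigError(Exception):
    """Base class for all package errors."""


class ConfigError(MycsigError):
    """Invalid or incomplete pipeline configuration (exit code 2)."""


class FormatError(MycsigError):
    """Malformed input file or invariant-violating data (exit code 3)."""


class ScoringError(MycsigError):
    """A score cannot be computed (insufficient overlap, constant
    direction vector, degenerate normalization; exit code 4)."""


class StatError(MycsigError):
    """A test statistic is undefined on the given data (exit code 4)."""


class ConvergenceError(StatError):
    """Partial-likelihood maximization diverged (e.g. complete separation
    of events between groups)."""
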