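"""Exception hierarchy shared across the package.

Validation errors mean the *input* is wrong (CLI exit code 1); computation
errors mean a numerically legitimate request could not be completed
(CLI exit code 2).
"""


class StromascanError(Exception):
    """Base class for all package errors."""


class ValidationError(StromascanError):
    """Malformed or contract-violating input."""


class ParseError(ValidationError):
    """A delimited file could not be parsed; message names the offending cell."""


class ComputationError(StromascanError):
    """A fit or search failed for numerical reasons."""


class ThresholdUnattainableError(ComputationError):
    """Greedy compaction shrank below the minimum size before every surviving
    gene's mean correlation cleared the threshold.

    Carries the :class:`~stromascan.metagene.CompactionTrace` accumulated up to
    the failure so callers can inspect near-misses.
    """

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace
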