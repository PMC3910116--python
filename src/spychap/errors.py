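"""Exception hierarchy.

Every error a caller is expected to handle derives from :class:`SpychapError`
so a pipeline driver can distinguish stage failures from programming bugs.
"""


class SpychapError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SpychapError, ValueError):
    """Input data or configuration violates a documented precondition."""


class GridMismatchError(InvalidInputError):
    """Two series that must share a sampling grid do not."""


class FitRejectedError(SpychapError):
    """A fit converged to a physically inadmissible solution, or failed to
    converge; the message names the diagnostic."""


class OutOfRangeError(SpychapError):
    """A readout or level falls outside the invertible/interpolable range;
    the message names the violated bound."""


class DataInconsistencyError(SpychapError):
    """Observed data contradict a physical constraint (e.g. a deuterated
    centroid lighter than its unlabeled partner beyond tolerance)."""
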