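"""Exception hierarchy for :mod:`mesn`.

Every error raised deliberately by the package derives from
:class:`MESNError`, so callers can distinguish domain failures
(degenerate reservoirs, invalid windows, singular readout systems)
from programming errors.
"""


class MESNError(Exception):
    """Base class for all mesn domain errors."""


class ConfigurationError(MESNError, ValueError):
    """A parameter combination violates its documented constraints."""


class ShapeError(MESNError, ValueError):
    """Array dimensions are inconsistent with the operation's contract."""


class DegenerateReservoirError(MESNError):
    """The unscaled recurrent matrix has spectral radius zero.

    Spectral-radius scaling is impossible; the reservoir would not
    satisfy the echo state property guard.
    """


class SingularSystemError(MESNError):
    """The ridge normal equations are singular (typically lambda = 0)."""


class EmptyInputError(MESNError, ValueError):
    """An input sequence or sample batch is empty."""


class InvalidWindowError(MESNError, ValueError):
    """The cropping window is longer than the trial."""


class ZeroNormError(MESNError, ValueError):
    """A channel with zero Euclidean norm cannot be L2-normalized."""


class EmptyBandError(MESNError, ValueError):
    """A frequency band contains no DFT bins at this length / rate."""


class DegenerateSignalError(MESNError, ValueError):
    """A channel carries zero energy in every retained band."""


class DegenerateFoldError(MESNError):
    """A training fold contains a single class; the readout is undefined."""


class InvalidSplitError(MESNError, ValueError):
    """Fewer samples than cross-validation folds."""


class UndefinedStatisticError(MESNError):
    """A requested statistic is undefined (e.g. CV with zero mean)."""
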