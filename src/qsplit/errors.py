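"""Exception hierarchy shared across the package.

Everything derives from :class:`QsplitError` so callers (and the CLI) can
distinguish data/parameter problems from genuine bugs with one except clause.
"""


class QsplitError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(QsplitError, ValueError):
    """A parameter violates its documented precondition."""


class IncompatibleAxesError(QsplitError):
    """Two spectra do not share an identical frequency axis."""


class OutOfRangeError(QsplitError):
    """A doublet component falls outside the spectral window."""


class AmbiguityError(QsplitError):
    """Residual-doublet identification found zero or several candidates."""

    def __init__(self, message, candidates=()):
        super().__init__(message)
        self.candidates = list(candidates)


class FragmentMismatchError(QsplitError):
    """Fragment labels or per-fragment splitting counts do not line up."""


class DegenerateGeometryError(QsplitError):
    """A bond vector has (numerically) zero length in some frame."""


class SelectionError(QsplitError):
    """An atom selection is empty, malformed, or refers to missing atoms."""


class UndefinedRelativeDeviationError(QsplitError):
    """An experimental splitting of exactly zero makes RMSRD undefined."""


class CandidateEvaluationError(QsplitError):
    """Trajectory provider failed for a candidate; carries its identity."""

    def __init__(self, message, candidate_seed=None):
        super().__init__(message)
        self.candidate_seed = candidate_seed


class TooShortPullError(QsplitError):
    """Pull trajectory spans less than one umbrella-window spacing."""


class DisconnectedHistogramError(QsplitError):
    """Umbrella windows leave unsampled gaps; WHAM cannot connect them."""

    def __init__(self, message, gaps=()):
        super().__init__(message)
        self.gaps = list(gaps)


class StructuralInputError(QsplitError):
    """Backbone atoms required for secondary-structure analysis are missing."""


class ConfigError(QsplitError):
    """Run configuration contains unknown keys or invalid values."""
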