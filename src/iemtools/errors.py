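"""Exception hierarchy for iemtools.

All errors derive from :class:`IEMToolsError` so callers can catch the
package's failures with a single except clause; the concrete subclasses
distinguish invalid parameters from genuine numerical degeneracies.
"""


class IEMToolsError(Exception):
    """Base class for all iemtools errors."""


class InvalidParameterError(IEMToolsError, ValueError):
    """A parameter is outside its documented domain."""


class SingularTransformError(IEMToolsError):
    """A channel transform is singular or numerically near-singular."""


class ConditioningError(IEMToolsError):
    """A random transform could not be drawn below the condition ceiling."""


class SingularFitError(IEMToolsError):
    """The forward channel-response matrix is rank deficient."""


class InversionError(IEMToolsError):
    """The weight Gram matrix W Wᵀ is singular; the model cannot be inverted."""


class AlignmentError(IEMToolsError):
    """A presented orientation does not coincide with a channel center / grid point."""


class ModalityError(IEMToolsError):
    """A curve does not have the modality the requested measure assumes."""


class ConvergenceError(IEMToolsError):
    """An iterative fit exhausted its budget without converging."""


class DegenerateDataError(IEMToolsError):
    """Input data are degenerate (e.g. zero residual variance)."""
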