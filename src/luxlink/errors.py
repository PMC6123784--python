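"""Exception hierarchy for luxlink.

Every error raised on a user-facing contract violation derives from
:class:`LuxlinkError`, so callers (and the CLI) can catch one base class
and map it to a nonzero exit code with a one-line reason.
"""


class LuxlinkError(Exception):
    """Base class for all luxlink errors."""


class ConfigurationError(LuxlinkError):
    """Invalid circuit topology, parameter set or run configuration."""


class InputDomainError(LuxlinkError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class NumericalStateError(LuxlinkError):
    """A dynamical state contains NaN or Inf; the message names the field."""


class IntegrationError(LuxlinkError):
    """The integrator produced an invalid state (reports time and field)."""


class CalibrationError(LuxlinkError):
    """No grid point produced enough peaks to estimate a period."""


class ResamplingError(LuxlinkError):
    """Requested resampling interval is finer than the native grid."""


class InsufficientPeaksError(LuxlinkError):
    """Too few detected peaks for the requested statistic."""


class NoMatchError(LuxlinkError):
    """No receiver peak could be matched to a sender peak."""


class EstimationError(LuxlinkError):
    """A statistical estimate is undefined for the given sample."""
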