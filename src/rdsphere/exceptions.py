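"""Exception hierarchy for rdsphere.

All errors raised by the library derive from :class:`RDSphereError` so callers
can catch them with a single ``except`` clause; the subclasses distinguish
invalid inputs from genuine mathematical singularities and numerical failures.
"""


class RDSphereError(Exception):
    """Base class for all rdsphere errors."""


class DomainError(RDSphereError, ValueError):
    """A parameter lies outside the mathematical domain of the operation
    (non-positive rate constant, radius outside [0, 1], negative time, ...)."""


class SingularPhiError(RDSphereError, ValueError):
    """The Thiele modulus coincides with an integer multiple of pi while the
    surface concentration is positive.  Neither the linearized steady state
    nor the analytical series solution is defined there; the method-of-lines
    solver remains applicable for transient profiles."""


class OverflowGuardError(RDSphereError, OverflowError):
    """A growing series exponent exceeds the double-precision range
    (exponent > 700).  In the erosion-controlled regime (Phi > pi) the
    solution grows like exp((Phi^2 - pi^2) * alpha * t); times this large lie
    far beyond the maximum reaction time t_max at which the constant
    ester-concentration assumption already fails."""


class NumericalError(RDSphereError, RuntimeError):
    """A numerical procedure (quadrature, ODE integration, series summation)
    failed to converge to the requested tolerance."""
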