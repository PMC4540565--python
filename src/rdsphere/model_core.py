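"""Parameters, nondimensionalization and the Thiele modulus.

The model describes a chemical species that is generated by a first-order
reaction (rate constant ``k``) while diffusing (diffusivity ``D``) inside a
sphere of radius ``R`` with a fixed surface concentration.  After normalizing
the radius to [0, 1] only two rate-like quantities remain:

* ``alpha = D / R**2`` — the inverse characteristic diffusion time, and
* ``k`` — the inverse characteristic reaction time,

whose ratio defines the Thiele modulus ``Phi = sqrt(k / alpha)``.  All
results of the model are functions of ``(Phi, alpha*t)`` (or ``k*t``), so a
parameter set may equivalently be specified as ``(k, D, R)`` or directly as
``(Phi, alpha)``.

Units are the caller's responsibility: any self-consistent time and length
units work, because the solution is dimensionless after normalization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Union

import numpy as np

from .exceptions import DomainError

__all__ = [
    "ModelParameters",
    "PolymerProperties",
    "thiele_modulus",
    "characteristic_alpha",
    "max_reaction_time",
]

#: An initial radial concentration profile: either a uniform positive scalar
#: or a bounded function of the normalized radius on [0, 1).
InitialProfile = Union[float, Callable[[np.ndarray], np.ndarray]]


def thiele_modulus(k: float, D: float, R: float) -> float:
    """Thiele modulus ``Phi = sqrt(k / (D / R**2))`` for a first-order
    reaction-diffusion system in a sphere of radius ``R``.

    ``Phi`` compares the characteristic time for diffusion, ``1/alpha``,
    with the characteristic time for reaction, ``1/k``; it scales linearly
    with the sphere radius.  ``Phi = pi`` separates bounded solutions from
    exponentially growing ones.

    Raises
    ------
    DomainError
        If any argument is not strictly positive.
    """
    if k <= 0 or D <= 0 or R <= 0:
        raise DomainError(f"k, D, R must be positive, got k={k}, D={D}, R={R}")
    return math.sqrt(k / characteristic_alpha(D, R))


def characteristic_alpha(D: float, R: float) -> float:
    """Inverse characteristic diffusion time ``alpha = D / R**2``.

    Raises
    ------
    DomainError
        If ``D`` or ``R`` is not strictly positive.
    """
    if D <= 0 or R <= 0:
        raise DomainError(f"D and R must be positive, got D={D}, R={R}")
    return D / R**2


@dataclass(frozen=True)
class PolymerProperties:
    """Molecular-weight inputs for the maximum-reaction-time bound.

    Attributes
    ----------
    M_n0 : float
        Initial number-average molecular weight of the polymer (Da).
    M_1 : float
        Average molecular weight of a monomer unit (Da).

    The ratio ``M_n0 / M_1`` equals the implied total-to-initial autocatalyst
    ratio ``(c_t0 + c_E) / c_t0`` when every ester bond has been hydrolyzed,
    where ``c_E`` is the (constant) ester-bond concentration absorbed into
    the rate constant.
    """

    M_n0: float
    M_1: float

    def __post_init__(self) -> None:
        if self.M_1 <= 0 or self.M_n0 <= 0:
            raise DomainError("molecular weights must be positive")
        if self.M_n0 < self.M_1:
            raise DomainError(
                f"M_n0 ({self.M_n0}) must be >= monomer weight M_1 ({self.M_1})"
            )

    @property
    def ester_ratio(self) -> float:
        """Implied ``(c_t0 + c_E) / c_t0 = M_n0 / M_1`` (dimensionless, >= 1).

        Inferred from the complete-conversion condition behind the maximum
        reaction time; the ester concentration ``c_E`` itself is never needed
        separately.
        """
        return self.M_n0 / self.M_1


def max_reaction_time(k: float, props: PolymerProperties) -> float:
    """Maximum reaction time ``t_max = (1/k) * ln(M_n0 / M_1)``.

    This is the time at which pure first-order growth of the autocatalyst
    would have converted every ester bond into a monomer; beyond it the
    constant ester-concentration assumption underlying first-order kinetics
    is violated.  Returns 0 when ``M_n0 == M_1``.

    Raises
    ------
    DomainError
        If ``k`` is not strictly positive.
    """
    if k <= 0:
        raise DomainError(f"rate constant k must be positive, got {k}")
    return math.log(props.ester_ratio) / k


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameter bundle for the sphere reaction-diffusion problem.

    Construct via :meth:`from_rates` (dimensional ``k, D, R``) or
    :meth:`from_dimensionless` (``phi, alpha``); both populate the derived
    fields consistently (``alpha = D/R**2``, ``phi**2 = k/alpha``).

    Attributes
    ----------
    k : float
        First-order generation rate constant (1/time), > 0.
    alpha : float
        Inverse characteristic diffusion time ``D/R**2`` (1/time), > 0.
    phi : float
        Thiele modulus ``sqrt(k/alpha)`` (dimensionless), > 0.
    D, R : float or None
        Dimensional diffusivity and radius when provided; ``None`` for the
        dimensionless parameterization.
    c_t0 : float or callable
        Initial concentration: a uniform scalar (> 0) or a bounded function
        of the normalized radius on [0, 1).
    c_r1 : float
        Fixed surface concentration (>= 0).  ``c_r1 <= c_t0`` corresponds to
        net flux toward the exterior (the physically typical case); larger
        values are permitted with a warning.
    """

    k: float
    alpha: float
    phi: float
    c_t0: InitialProfile
    c_r1: float = 0.0
    D: float | None = field(default=None, compare=False)
    R: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.k <= 0 or self.alpha <= 0 or self.phi <= 0:
            raise DomainError(
                f"k, alpha, phi must be positive "
                f"(k={self.k}, alpha={self.alpha}, phi={self.phi})"
            )
        if self.c_r1 < 0:
            raise DomainError(f"surface concentration c_r1 must be >= 0, got {self.c_r1}")
        if self.uniform_initial:
            if self.c_t0 <= 0:
                raise DomainError(f"uniform c_t0 must be > 0, got {self.c_t0}")
            if self.c_r1 > self.c_t0:
                warnings.warn(
                    "c_r1 > c_t0: net flux is toward the interior; the usual "
                    "physical case has c_r1 <= c_t0",
                    stacklevel=3,
                )

    @classmethod
    def from_rates(
        cls,
        k: float,
        D: float,
        R: float,
        c_t0: InitialProfile = 1.0,
        c_r1: float = 0.0,
    ) -> "ModelParameters":
        """Build from the dimensional parameters ``(k, D, R)``."""
        alpha = characteristic_alpha(D, R)
        phi = thiele_modulus(k, D, R)
        return cls(k=k, alpha=alpha, phi=phi, c_t0=c_t0, c_r1=c_r1, D=D, R=R)

    @classmethod
    def from_dimensionless(
        cls,
        phi: float,
        alpha: float = 1.0,
        c_t0: InitialProfile = 1.0,
        c_r1: float = 0.0,
    ) -> "ModelParameters":
        """Build from ``(Phi, alpha)``; the rate constant is ``k = Phi**2 * alpha``."""
        if phi <= 0 or alpha <= 0:
            raise DomainError(f"phi and alpha must be positive (phi={phi}, alpha={alpha})")
        return cls(k=phi**2 * alpha, alpha=alpha, phi=phi, c_t0=c_t0, c_r1=c_r1)

    @property
    def uniform_initial(self) -> bool:
        """Whether the initial condition is a uniform scalar."""
        return not callable(self.c_t0)

    def initial_profile(self, r: np.ndarray | float) -> np.ndarray:
        """Evaluate the initial concentration ``c_t0(r)`` on ``r`` in [0, 1)."""
        r = np.asarray(r, dtype=float)
        if self.uniform_initial:
            return np.full_like(r, float(self.c_t0))
        return np.asarray(self.c_t0(r), dtype=float)
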