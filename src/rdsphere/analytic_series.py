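"""Closed-form transient solution by steady-state + eigenfunction expansion.

The dimensionless problem

.. math::

    \\partial_t c = \\frac{\\alpha}{r^2}\\partial_r(r^2 \\partial_r c) + k c,
    \\qquad \\partial_r c(0,t)=0,\\quad c(1,t)=c_{r1},\\quad c(r,0)=c_{t0}(r)

is solved through the substitution ``v = r c``, which turns the spherical
Laplacian into a plane one.  ``v`` splits into the steady solution of the
linearized problem, ``u(r) = c_r1 sin(Phi r)/sin(Phi)``, plus a transient
remainder expanded in the Dirichlet eigenfunctions ``sin(n pi r)``.  Each
mode evolves independently with rate ``lambda_n = (n^2 pi^2 - Phi^2) alpha``:
all modes decay when the Thiele modulus ``Phi < pi``; the ``n = 1`` mode
grows exponentially when ``Phi > pi``; and at the tipping point ``Phi = pi``
the leading mode is neutrally stable, leaving a nontrivial long-time profile.

For ``c_r1 > 0`` the solution is undefined whenever ``Phi`` is an integer
multiple of pi (the steady part and the mode coefficients both blow up);
those transient profiles must be computed with the finite-difference solver
in :mod:`rdsphere.mol_solver` instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import integrate

from .exceptions import (
    DomainError,
    NumericalError,
    OverflowGuardError,
    SingularPhiError,
)
from .model_core import ModelParameters

__all__ = [
    "SeriesExpansion",
    "steady_state",
    "fourier_coefficient_uniform",
    "fourier_coefficient_general",
    "concentration",
    "is_singular_phi",
]

#: Relative tolerance within which Phi counts as an integer multiple of pi.
SINGULARITY_RTOL = 1e-9
#: Radii below this are evaluated with the analytic r -> 0 limit.
CENTER_EPS = 1e-12
#: Relative magnitude below which adaptive summation terminates.
TRUNCATION_RTOL = 1e-12
#: Hard cap on the number of series terms.
MAX_TERMS = 10_000
#: Largest admissible growing exponent before double-precision overflow.
OVERFLOW_EXPONENT = 700.0


def is_singular_phi(phi: float, rtol: float = SINGULARITY_RTOL) -> bool:
    """True when ``phi`` lies within relative tolerance of ``m * pi`` for some
    positive integer ``m`` (where the ``c_r1 > 0`` solution is undefined)."""
    m = round(phi / math.pi)
    return m >= 1 and abs(phi - m * math.pi) < rtol * max(1.0, phi)


def _check_singular(phi: float, c_r1: float) -> None:
    if c_r1 > 0 and is_singular_phi(phi):
        raise SingularPhiError(
            f"Phi = {phi!r} is within tolerance of an integer multiple of pi "
            "with c_r1 > 0: neither the linearized steady state nor the "
            "analytical solution is defined; use the method-of-lines solver "
            "for transient profiles"
        )


def steady_state(r, phi: float, c_r1: float):
    """Steady concentration ``c_r1 sin(Phi r) / (r sin Phi)`` of the
    linearized problem, with the limit value ``c_r1 Phi / sin(Phi)`` at the
    center.

    Identically zero when ``c_r1 = 0`` (the trivial steady state).  Equals
    ``c_r1`` exactly at the surface ``r = 1``.

    Raises
    ------
    SingularPhiError
        If ``c_r1 > 0`` and ``Phi`` is within tolerance of ``m * pi``.
    DomainError
        If ``Phi <= 0`` or any radius lies outside [0, 1].
    """
    if phi <= 0:
        raise DomainError(f"Phi must be positive, got {phi}")
    r_arr = np.asarray(r, dtype=float)
    if np.any((r_arr < 0) | (r_arr > 1)):
        raise DomainError("radius must lie in [0, 1]")
    if c_r1 == 0:
        out = np.zeros_like(r_arr)
        return out if out.ndim else float(out)
    _check_singular(phi, c_r1)
    # sin(phi*r)/r == phi * sinc(phi*r/pi); finite at r = 0 by construction.
    out = c_r1 * phi * np.sinc(phi * r_arr / np.pi) / math.sin(phi)
    return out if out.ndim else float(out)


def fourier_coefficient_uniform(n: int, phi: float, c_t0: float, c_r1: float) -> float:
    """Initial generalized Fourier coefficient ``a_n(0)`` for a uniform
    initial concentration::

        a_n(0) = -2 c_t0 (-1)^n / (n pi)  +  2 c_r1 n pi (-1)^n / (n^2 pi^2 - Phi^2)

    When ``c_r1 = 0`` the second term is defined as zero even at a vanishing
    denominator (the ``c_t0`` part is regular at ``Phi = m pi``).
    """
    if n < 1:
        raise DomainError(f"mode index n must be >= 1, got {n}")
    sign = -1.0 if n % 2 else 1.0
    term = -2.0 * c_t0 * sign / (n * math.pi)
    if c_r1 != 0:
        denom = (n * math.pi) ** 2 - phi**2
        if abs(denom) < SINGULARITY_RTOL * (n * math.pi) ** 2:
            raise SingularPhiError(
                f"mode n={n}: resonant denominator n^2 pi^2 - Phi^2 vanishes "
                f"at Phi={phi!r} with c_r1 > 0"
            )
        term += 2.0 * c_r1 * n * math.pi * sign / denom
    return term


def fourier_coefficient_general(
    n: int,
    phi: float,
    c_t0_profile: Callable[[np.ndarray], np.ndarray] | float,
    c_r1: float,
) -> float:
    """Initial coefficient ``a_n(0)`` for an arbitrary bounded initial
    profile, by orthogonality of the sine eigenfunctions::

        a_n(0) = int_0^1 2 r c_t0(r) sin(n pi r) dr
                 + 2 c_r1 n pi (-1)^n / (n^2 pi^2 - Phi^2)

    The integral is computed by adaptive quadrature to absolute tolerance
    1e-10.  A uniform scalar profile delegates to the closed form.
    """
    if not callable(c_t0_profile):
        return fourier_coefficient_uniform(n, phi, float(c_t0_profile), c_r1)
    if n < 1:
        raise DomainError(f"mode index n must be >= 1, got {n}")
    val, err = integrate.quad(
        lambda r: 2.0 * r * float(c_t0_profile(r)) * math.sin(n * math.pi * r),
        0.0,
        1.0,
        epsabs=1e-10,
        limit=200,
    )
    if err > 1e-8:
        raise NumericalError(
            f"quadrature for mode n={n} did not converge (error estimate {err:g})"
        )
    if c_r1 != 0:
        denom = (n * math.pi) ** 2 - phi**2
        if abs(denom) < SINGULARITY_RTOL * (n * math.pi) ** 2:
            raise SingularPhiError(
                f"mode n={n}: resonant denominator vanishes at Phi={phi!r} with c_r1 > 0"
            )
        sign = -1.0 if n % 2 else 1.0
        val += 2.0 * c_r1 * n * math.pi * sign / denom
    return val


@dataclass(frozen=True)
class SeriesExpansion:
    """Frozen truncated expansion of the transformed transient problem.

    Attributes
    ----------
    phi, c_r1 : float
        Thiele modulus and surface concentration of the underlying problem.
    coefficients : ndarray
        Initial coefficients ``a_n(0)`` for ``n = 1..n_terms`` (units of the
        transformed variable ``v = r c``).
    rates : ndarray
        Decay (or growth, if negative) rates ``lambda_n = (n^2 pi^2 - Phi^2)
        alpha`` in 1/time; strictly increasing in ``n``, all positive iff
        ``Phi < pi``.
    n_terms : int
        Truncation order.
    """

    phi: float
    c_r1: float
    coefficients: np.ndarray
    rates: np.ndarray
    n_terms: int

    @classmethod
    def from_parameters(cls, params: ModelParameters, n_terms: int) -> "SeriesExpansion":
        """Build the first ``n_terms`` modes for a parameter bundle."""
        if n_terms < 1:
            raise DomainError(f"n_terms must be >= 1, got {n_terms}")
        _check_singular(params.phi, params.c_r1)
        n = np.arange(1, n_terms + 1)
        if params.uniform_initial:
            sign = np.where(n % 2 == 1, -1.0, 1.0)
            coeff = -2.0 * float(params.c_t0) * sign / (n * np.pi)
            if params.c_r1 != 0:
                denom = (n * np.pi) ** 2 - params.phi**2
                coeff = coeff + 2.0 * params.c_r1 * n * np.pi * sign / denom
        else:
            coeff = np.array(
                [
                    fourier_coefficient_general(int(m), params.phi, params.c_t0, params.c_r1)
                    for m in n
                ]
            )
        rates = ((n * np.pi) ** 2 - params.phi**2) * params.alpha
        return cls(
            phi=params.phi,
            c_r1=params.c_r1,
            coefficients=coeff,
            rates=rates,
            n_terms=n_terms,
        )

    def evaluate(self, r: np.ndarray, t: float) -> np.ndarray:
        """Sum the truncated series ``sum_n a_n(0) e^{-lambda_n t} sin(n pi r)/r``
        on radii ``r`` (the center limit substitutes ``n pi`` for
        ``sin(n pi r)/r``) and add the steady part."""
        exponents = -self.rates * t
        if exponents.size and exponents.max() > OVERFLOW_EXPONENT:
            raise OverflowGuardError(
                f"series exponent {exponents.max():.1f} exceeds {OVERFLOW_EXPONENT:g}: "
                "the solution has grown beyond double precision; in this "
                "erosion-controlled regime (Phi > pi) restrict t to the "
                "maximum reaction time t_max = ln(M_n0/M_1)/k"
            )
        n = np.arange(1, self.n_terms + 1)
        # sin(n pi r)/r = n pi sinc(n r): finite at r = 0, zero at r = 1.
        radial = n[:, None] * np.pi * np.sinc(n[:, None] * r[None, :])
        series = (self.coefficients * np.exp(exponents)) @ radial
        return series + steady_state(r, self.phi, self.c_r1)


def _adaptive_series(r: np.ndarray, t: float, params: ModelParameters) -> np.ndarray:
    """Sum the eigenfunction series adaptively: terms are added in blocks
    until two consecutive terms fall below ``TRUNCATION_RTOL`` relative to
    the running partial sum (the exponential factor decays monotonically in
    ``n`` for ``t > 0``, so trailing terms cannot resurge)."""
    alpha_t = params.alpha * t
    phi = params.phi
    total = np.zeros_like(r)
    block = 64
    n0 = 1
    small_streak = 0
    while n0 <= MAX_TERMS:
        n = np.arange(n0, min(n0 + block, MAX_TERMS + 1))
        sign = np.where(n % 2 == 1, -1.0, 1.0)
        if params.uniform_initial:
            coeff = -2.0 * float(params.c_t0) * sign / (n * np.pi)
        else:
            coeff = np.array(
                [
                    fourier_coefficient_general(int(m), phi, params.c_t0, 0.0)
                    for m in n
                ]
            )
        if params.c_r1 != 0:
            denom = (n * np.pi) ** 2 - phi**2
            coeff = coeff + 2.0 * params.c_r1 * n * np.pi * sign / denom
        exponents = -((n * np.pi) ** 2 - phi**2) * alpha_t
        if exponents[0] > OVERFLOW_EXPONENT:
            raise OverflowGuardError(
                f"series exponent {exponents[0]:.1f} exceeds {OVERFLOW_EXPONENT:g} "
                "(growing mode, Phi > pi): the solution overflows double "
                "precision; restrict t to the reaction-dominant bound "
                "t_max = ln(M_n0/M_1)/k"
            )
        weights = coeff * np.exp(exponents)
        radial = n[:, None] * np.pi * np.sinc(n[:, None] * r[None, :])
        terms = weights[:, None] * radial
        # |sin(n pi r)/r| <= n pi, so n pi |weight| bounds the term everywhere.
        bounds = np.abs(weights) * n * np.pi
        scale = TRUNCATION_RTOL * max(1.0, float(np.abs(total).max(initial=0.0)))
        for j in range(len(n)):
            total += terms[j]
            small_streak = small_streak + 1 if bounds[j] < scale else 0
            if small_streak >= 2:
                return total
        n0 += block
    raise NumericalError(
        f"series did not converge within {MAX_TERMS} terms (alpha*t={alpha_t:g}, "
        f"Phi={phi:g}); for t near 0 use the initial profile directly"
    )


def concentration(r, t: float, params: ModelParameters, n_terms: int | None = None):
    """Transient autocatalyst concentration ``c(r, t)`` from the analytical
    series solution.

    Parameters
    ----------
    r : float or array-like
        Normalized radii in [0, 1].
    t : float
        Time (>= 0) in the units implied by ``params`` (``alpha`` and ``k``
        carry the time scale).
    params : ModelParameters
        Problem parameters; the initial condition may be uniform or an
        arbitrary bounded radial profile.
    n_terms : int, optional
        Fixed truncation order.  By default the series is truncated
        adaptively: summation stops once terms fall below 1e-12 relative to
        the partial sum (hard cap 10,000 terms); the factor
        ``exp(-n^2 pi^2 alpha t)`` makes this rapid for any ``t > 0``.

    Notes
    -----
    ``t = 0`` short-circuits to the supplied initial profile: the series does
    converge to it pointwise, but only slowly (Gibbs oscillation at the
    surface when ``c_t0(1) != c_r1``), so summing it there is numerically
    pathological.  ``r = 1`` returns exactly ``c_r1`` for ``t > 0``, and the
    center value uses the analytic ``sin(n pi r)/r -> n pi`` limit.

    Raises
    ------
    SingularPhiError
        If ``c_r1 > 0`` and ``Phi`` is within tolerance of ``m * pi``.
    OverflowGuardError
        If a growing exponent (``Phi > pi``) exceeds the double-precision
        range; such times lie beyond the model's validity anyway.
    """
    if t < 0:
        raise DomainError(f"time must be >= 0, got {t}")
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    scalar = np.ndim(r) == 0
    if np.any((r_arr < 0) | (r_arr > 1)):
        raise DomainError("radius must lie in [0, 1]")
    _check_singular(params.phi, params.c_r1)

    surface = np.isclose(r_arr, 1.0, rtol=0.0, atol=CENTER_EPS)
    if t == 0:
        out = params.initial_profile(r_arr)
        out[surface] = params.c_r1
    else:
        if n_terms is not None:
            expansion = SeriesExpansion.from_parameters(params, n_terms)
            out = expansion.evaluate(r_arr, t)
        else:
            out = _adaptive_series(r_arr, t, params) + steady_state(
                r_arr, params.phi, params.c_r1
            )
        out[surface] = params.c_r1
    return float(out[0]) if scalar else out
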