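"""Reaction- and diffusion-dominant limits and Thiele-modulus regimes.

Dropping the diffusion term from the conservation equation leaves pure
first-order growth, ``c_rxn = c_t0 exp(k t)`` — the classical well-mixed
treatment of autocatalytic hydrolysis and an upper bound on the full
solution.  Dropping the reaction term leaves pure diffusion in a sphere,
whose series solution ``c_diffn`` is the lower bound.  For a uniform initial
condition with ``c_r1 = 0`` the full solution factorizes exactly as
``c = exp(k t) * c_diffn``, which is why the two limits bracket it for every
Thiele modulus.

``Phi = pi`` is the tipping point: below it every series mode decays and the
sphere reaches a steady state (release is diffusion-controlled); at or above
it the leading mode is neutral or growing and the interior runs away
(erosion-controlled).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError
from .analytic_series import (
    CENTER_EPS,
    MAX_TERMS,
    TRUNCATION_RTOL,
    is_singular_phi,
)

__all__ = [
    "RegimeReport",
    "reaction_limit",
    "diffusion_limit",
    "classify_regime",
    "steady_state_exists",
    "largest_bounded_phi",
]

DIFFUSION_CONTROLLED = "diffusion-controlled"
EROSION_CONTROLLED = "erosion-controlled"


@dataclass(frozen=True)
class RegimeReport:
    """Classification of a Thiele modulus.

    Attributes
    ----------
    phi : float
        The Thiele modulus classified.
    regime : str
        ``"diffusion-controlled"`` iff ``Phi < pi``; ``"erosion-controlled"``
        iff ``Phi >= pi`` (the boundary itself belongs to the closed bound).
    steady_state_exists : bool
        True iff every series exponent is non-growing, i.e. ``Phi <= pi``.
    steady_state_kind : str
        One of ``"trivial-zero"`` (``c_r1 = 0``, ``Phi < pi``: everything
        diffuses out), ``"nontrivial"`` (a finite nonzero profile),
        ``"undefined"`` (``c_r1 > 0`` at ``Phi = m pi``, where the linearized
        steady state blows up) or ``"none"`` (``Phi > pi``: runaway growth).
    is_tipping_point : bool
        True when ``Phi`` equals pi exactly, the boundary between the two
        regimes.  The regime comparison uses exact pi; probe near-pi behavior
        through :func:`steady_state_exists`, which applies the singularity
        tolerance of the series module.
    """

    phi: float
    regime: str
    steady_state_exists: bool
    steady_state_kind: str
    is_tipping_point: bool = False


def reaction_limit(t, k: float, c_t0: float):
    """Reaction-dominant limit ``c_rxn = c_t0 exp(k t)`` — first-order growth
    with diffusion neglected; independent of radius, and the upper bound
    approached by the full solution as ``Phi -> infinity``."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("time must be >= 0")
    out = c_t0 * np.exp(k * t_arr)
    return out if out.ndim else float(out)


def diffusion_limit(r, t: float, alpha: float, c_t0: float, c_r1: float = 0.0):
    """Diffusion-dominant limit ``c_diffn(r, t)`` — transient diffusion in a
    sphere with the reaction neglected::

        c_diffn(0, t) = c_r1 + 2 (c_r1 - c_t0) sum_n (-1)^n e^{-n^2 pi^2 alpha t}
        c_diffn(r, t) = c_r1 + (2 (c_r1 - c_t0) / (pi r))
                        sum_n ((-1)^n / n) e^{-n^2 pi^2 alpha t} sin(n pi r)

    Lower bound on the full solution; approached as ``Phi -> 0``.  ``t = 0``
    short-circuits to the uniform initial value ``c_t0`` (``c_r1`` at the
    surface), and the truncation policy matches the full series solution.
    """
    if t < 0:
        raise DomainError(f"time must be >= 0, got {t}")
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    scalar = np.ndim(r) == 0
    if np.any((r_arr < 0) | (r_arr > 1)):
        raise DomainError("radius must lie in [0, 1]")
    surface = np.isclose(r_arr, 1.0, rtol=0.0, atol=CENTER_EPS)
    if t == 0:
        out = np.full_like(r_arr, c_t0)
        out[surface] = c_r1
        return float(out[0]) if scalar else out

    total = np.zeros_like(r_arr)
    amp = 2.0 * (c_r1 - c_t0)
    block = 64
    n0 = 1
    small_streak = 0
    while n0 <= MAX_TERMS and small_streak < 2:
        n = np.arange(n0, min(n0 + block, MAX_TERMS + 1))
        sign = np.where(n % 2 == 1, -1.0, 1.0)
        weights = amp * sign * np.exp(-((n * np.pi) ** 2) * alpha * t) / (n * np.pi)
        # sin(n pi r)/r with the n pi center limit, via the sinc identity.
        radial = n[:, None] * np.pi * np.sinc(n[:, None] * r_arr[None, :])
        terms = weights[:, None] * radial
        bounds = np.abs(weights) * n * np.pi
        scale = TRUNCATION_RTOL * max(1.0, float(np.abs(total).max(initial=0.0)))
        for j in range(len(n)):
            total += terms[j]
            small_streak = small_streak + 1 if bounds[j] < scale else 0
            if small_streak >= 2:
                break
        n0 += block
    out = c_r1 + total
    out[surface] = c_r1
    return float(out[0]) if scalar else out


def steady_state_exists(phi: float, c_r1: float = 0.0) -> tuple[bool, str]:
    """Whether the transient solution admits a steady state, and of what kind.

    A steady state requires every series exponent to be non-growing:
    ``n^2 pi^2 - Phi^2 >= 0`` for all ``n >= 1``, which the ``n = 1`` mode
    restricts to ``Phi <= pi``.

    Returns ``(exists, kind)`` with ``kind`` as documented on
    :class:`RegimeReport`.  The ``Phi = m pi`` comparison applies the series
    module's singularity tolerance.
    """
    if phi <= 0:
        raise DomainError(f"Phi must be positive, got {phi}")
    if c_r1 < 0:
        raise DomainError(f"c_r1 must be >= 0, got {c_r1}")
    singular = is_singular_phi(phi)
    at_pi = singular and round(phi / math.pi) == 1
    exists = phi <= math.pi or at_pi
    if not exists:
        return False, "none"
    if c_r1 == 0:
        return True, "nontrivial" if at_pi else "trivial-zero"
    return True, "undefined" if at_pi else "nontrivial"


def classify_regime(phi: float, c_r1: float = 0.0) -> RegimeReport:
    """Classify a Thiele modulus into the diffusion- or erosion-controlled
    regime and report steady-state existence.

    ``Phi < pi`` is diffusion-controlled; ``Phi >= pi`` is erosion-controlled
    (closed bound), with ``Phi = pi`` flagged as the tipping point — the one
    value that is erosion-controlled by the bound yet still admits a steady
    state.
    """
    if phi <= 0:
        raise DomainError(f"Phi must be positive, got {phi}")
    exists, kind = steady_state_exists(phi, c_r1)
    return RegimeReport(
        phi=phi,
        regime=DIFFUSION_CONTROLLED if phi < math.pi else EROSION_CONTROLLED,
        steady_state_exists=exists,
        steady_state_kind=kind,
        is_tipping_point=(phi == math.pi),
    )


def largest_bounded_phi(phi_max: float = 5.0, resolution: float = 1e-6) -> float:
    """Scan ``Phi`` over ``(0, phi_max]`` at the given resolution and return
    the largest value for which no series exponent grows.

    The most restrictive mode is ``n = 1``, whose exponent ``(pi^2 - Phi^2)
    alpha`` first turns negative above ``Phi = pi``; the scan therefore
    resolves the boundedness threshold to within ``resolution``.
    """
    if phi_max <= 0 or resolution <= 0:
        raise DomainError("phi_max and resolution must be positive")
    phis = np.arange(resolution, phi_max + resolution / 2, resolution)
    # growing mode exists iff the n = 1 exponent is negative
    bounded = (np.pi**2 - phis**2) >= 0
    if not bounded.any():
        raise DomainError(f"no bounded Phi found below {phi_max}")
    return float(phis[bounded][-1])
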