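import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rdsphere import (
    DomainError,
    ModelParameters,
    OverflowGuardError,
    SeriesExpansion,
    SingularPhiError,
    concentration,
    fourier_coefficient_general,
    fourier_coefficient_uniform,
    steady_state,
)

PI = math.pi


class TestSteadyState:
    @pytest.mark.parametrize(
        "r, phi, c_r1, expected",
        [
            (1.0, 2.0, 2.0, 2.0),  # surface boundary condition
            (0.0, PI / 2, 1.0, PI / 2),  # center limit: phi / sin(phi)
            # interior closed form sin(phi r) / (r sin phi)
            (0.5, 0.75 * PI, 1.0, math.sin(0.375 * PI) / (0.5 * math.sin(0.75 * PI))),
        ],
    )
    def test_closed_form_values(self, r, phi, c_r1, expected):
        assert steady_state(r, phi, c_r1) == pytest.approx(expected, rel=1e-12)

    def test_zero_surface_gives_trivial_steady_state(self):
        r = np.linspace(0, 1, 11)
        assert np.all(steady_state(r, 2.5 * PI, 0.0) == 0.0)

    def test_singular_phi_with_positive_surface_rejected(self):
        for m in (1, 2):
            with pytest.raises(SingularPhiError):
                steady_state(0.5, m * PI, 1.0)
        # c_r1 = 0 remains evaluable at the resonance
        assert steady_state(0.5, PI, 0.0) == 0.0

    def test_domain_checks(self):
        with pytest.raises(DomainError):
            steady_state(1.5, 1.0, 1.0)
        with pytest.raises(DomainError):
            steady_state(0.5, -1.0, 1.0)


class TestFourierCoefficients:
    @pytest.mark.parametrize(
        "n, phi, c_t0, c_r1, expected",
        [
            (1, 0.5 * PI, 1.0, 0.0, 2 / PI),
            (2, 0.5 * PI, 1.0, 0.0, -1 / PI),
            # pure-boundary part: -2 pi / (pi^2 - pi^2/4) = -8 / (3 pi)
            (1, 0.5 * PI, 0.0, 1.0, -8 / (3 * PI)),
        ],
    )
    def test_uniform_values(self, n, phi, c_t0, c_r1, expected):
        got = fourier_coefficient_uniform(n, phi, c_t0, c_r1)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_uniform_alternates_and_decays_without_surface_term(self):
        coeffs = [fourier_coefficient_uniform(n, 0.5 * PI, 1.0, 0.0) for n in range(1, 20)]
        signs = np.sign(coeffs)
        assert np.all(signs[::2] == 1) and np.all(signs[1::2] == -1)
        assert np.all(np.diff(np.abs(coeffs)) < 0)

    def test_resonant_denominator_with_surface_rejected(self):
        with pytest.raises(SingularPhiError):
            fourier_coefficient_uniform(2, 2 * PI, 1.0, 1.0)
        # defined as zero when c_r1 = 0
        got = fourier_coefficient_uniform(2, 2 * PI, 1.0, 0.0)
        assert got == pytest.approx(-2 * 1.0 / (2 * PI), rel=1e-12)

    def test_general_matches_uniform_closed_form(self):
        for n in range(1, 6):
            got = fourier_coefficient_general(n, 0.5 * PI, lambda r: 1.0, 0.0)
            want = fourier_coefficient_uniform(n, 0.5 * PI, 1.0, 0.0)
            assert got == pytest.approx(want, abs=1e-10)

    def test_single_mode_profile_by_orthogonality(self):
        """c_t0(r) = sin(pi r)/r puts all initial content in mode 1:
        a_1 = int 2 sin^2(pi r) dr = 1 and a_2 = 0."""
        profile = lambda r: PI * np.sinc(r)  # sin(pi r)/r, finite at 0
        assert fourier_coefficient_general(1, 0.5 * PI, profile, 0.0) == pytest.approx(
            1.0, abs=1e-9
        )
        assert fourier_coefficient_general(2, 0.5 * PI, profile, 0.0) == pytest.approx(
            0.0, abs=1e-9
        )


class TestConcentration:
    def test_tipping_point_center_limit_is_two(self, params_factory):
        """At Phi = pi with c_r1 = 0 the neutral n = 1 mode survives and the
        center concentration balances at 2 c_t0."""
        params = params_factory(1.0)
        assert concentration(0.0, 5.0, params) == pytest.approx(2.0, abs=1e-10)

    def test_initial_condition_short_circuit(self, params_factory):
        params = params_factory(0.5, c_t0=1.0, c_r1=1.0)
        assert concentration(0.5, 0.0, params) == 1.0

    def test_subcritical_center_value(self, params_factory):
        """Brute-force 100-term summation of the uniform-IC center series as
        an independent oracle at Phi = pi/2, alpha t = 0.5."""
        params = params_factory(0.5)
        n = np.arange(1, 101)
        oracle = 2.0 * np.sum((-1.0) ** (n + 1) * np.exp(-(n**2 - 0.25) * PI**2 * 0.5))
        assert oracle == pytest.approx(0.0494, abs=1e-4)
        assert concentration(0.0, 0.5, params) == pytest.approx(oracle, rel=1e-10)

    def test_surface_value_exact(self, params_factory):
        params = params_factory(0.75, c_r1=0.25)
        for t in (0.01, 0.5, 3.0):
            assert concentration(1.0, t, params) == 0.25

    def test_center_is_symmetric(self, params_factory):
        """The finite-difference slope at r = 0 vanishes as the stencil
        shrinks (zero-flux symmetry at the center)."""
        params = params_factory(0.75)
        slopes = []
        for h in (1e-2, 1e-3, 1e-4):
            c0 = concentration(0.0, 0.3, params)
            ch = concentration(h, 0.3, params)
            slopes.append(abs(ch - c0) / h)
        assert slopes[-1] < 1e-2 and slopes[-1] < slopes[0]

    def test_pde_residual_vanishes_under_refinement(self, params_factory):
        """A centered discretization of dc/dt = alpha/r^2 (r^2 c_r)_r + k c
        applied to the series solution has residual -> 0 as the grid refines."""
        params = params_factory(0.75)
        t, residuals = 0.3, []
        for h in (1e-2, 1e-3):
            r = np.arange(0.2, 0.81, 0.1)
            c = lambda rr, tt: concentration(rr, tt, params)
            dc_dt = (c(r, t + h * h) - c(r, t - h * h)) / (2 * h * h)
            lap = (
                c(r + h, t) - 2 * c(r, t) + c(r - h, t)
            ) / h**2 + (2 / r) * (c(r + h, t) - c(r - h, t)) / (2 * h)
            res = dc_dt - params.alpha * lap - params.k * c(r, t)
            residuals.append(np.abs(res).max())
        assert residuals[-1] < 1e-3 and residuals[-1] < residuals[0] / 10

    def test_steady_state_convergence_with_surface_source(self, params_factory):
        """For Phi < pi and c_r1 > 0 the transient solution relaxes to the
        closed-form linearized steady state."""
        params = params_factory(0.5, c_r1=1.0)
        r = np.linspace(0, 1, 21)
        got = concentration(r, 20.0, params)
        want = steady_state(r, params.phi, params.c_r1)
        assert np.abs(got - want).max() < 1e-8

    def test_long_time_limits_zero_surface(self, params_factory):
        r = np.linspace(0, 1, 11)
        sub = concentration(r, 20.0, params_factory(0.5))
        assert np.abs(sub).max() < 1e-8  # everything diffuses out
        tip = concentration(0.0, 20.0, params_factory(1.0))
        assert tip == pytest.approx(2.0, abs=1e-12)  # nontrivial balance

    def test_truncation_is_converged(self, params_factory):
        """Adding 50 more terms beyond the fixed truncation changes nothing
        above 1e-10 for alpha t >= 0.01."""
        params = params_factory(0.75, c_r1=0.3)
        r = np.linspace(0, 1, 11)
        for t in (0.01, 0.1, 1.0):
            a = SeriesExpansion.from_parameters(params, 120).evaluate(r, t)
            b = SeriesExpansion.from_parameters(params, 170).evaluate(r, t)
            assert np.abs(a - b).max() < 1e-10
            adaptive = concentration(r, t, params)
            assert np.abs(adaptive - b).max() < 1e-9

    def test_decay_rates_strictly_increasing_and_sign(self, params_factory):
        exp_sub = SeriesExpansion.from_parameters(params_factory(0.9), 50)
        assert np.all(np.diff(exp_sub.rates) > 0)
        assert np.all(exp_sub.rates > 0)  # Phi < pi: all modes decay
        exp_super = SeriesExpansion.from_parameters(params_factory(1.25), 50)
        assert exp_super.rates[0] < 0  # growing leading mode
        assert np.all(exp_super.rates[1:] > 0)

    def test_singular_surface_configuration_rejected(self, params_factory):
        params = params_factory(1.0, c_r1=1.0)
        with pytest.raises(SingularPhiError):
            concentration(0.5, 0.5, params)

    def test_overflow_guard_in_growth_regime(self, params_factory):
        """For Phi = 5 pi the leading exponent (Phi^2 - pi^2) alpha t passes
        700 near alpha t = 2.96; beyond that an explicit error points at the
        reaction-time bound instead of silently overflowing."""
        params = params_factory(5.0)
        concentration(0.0, 0.1, params)  # fine well below the guard
        with pytest.raises(OverflowGuardError):
            concentration(0.0, 3.0, params)

    def test_nonuniform_initial_profile_single_mode(self):
        """With v(r, 0) = sin(pi r) only mode 1 is populated, so the solution
        is sin(pi r)/r * exp(-(pi^2 - Phi^2) alpha t) exactly."""
        params = ModelParameters.from_dimensionless(
            phi=0.5 * PI, c_t0=lambda r: PI * np.sinc(r), c_r1=0.0
        )
        r = np.array([0.0, 0.3, 0.7])
        t = 0.2
        want = PI * np.sinc(r) * math.exp(-(PI**2 - params.phi**2) * t)
        got = concentration(r, t, params)
        assert got == pytest.approx(want, rel=1e-8)

    def test_domain_checks(self, params_factory):
        params = params_factory(0.5)
        with pytest.raises(DomainError):
            concentration(0.5, -1.0, params)
        with pytest.raises(DomainError):
            concentration(1.5, 1.0, params)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    phi_over_pi=st.floats(0.05, 0.99),
    c_r1=st.floats(0.0, 1.0),
    t=st.floats(0.05, 2.0),
)
def test_surface_boundary_condition_always_holds(phi_over_pi, c_r1, t):
    params = ModelParameters.from_dimensionless(
        phi=phi_over_pi * PI, c_t0=1.0, c_r1=c_r1
    )
    assert concentration(1.0, t, params) == c_r1
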