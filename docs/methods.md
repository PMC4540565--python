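# Methods

## Model

The package solves the conservation equation for a species undergoing
simultaneous diffusion and first-order generation inside a radially
symmetric sphere with the radius normalized to [0, 1]:

    ∂c/∂t = (α/r²) ∂/∂r(r² ∂c/∂r) + k c,        α = D/R²,  k > 0,

with symmetry at the center (∂c/∂r = 0 at r = 0), a fixed surface
concentration c(1, t) = c_r1 ≥ 0, and an initial distribution
c(r, 0) = c_t0(r) > 0. The intended physical system is the autocatalytic
carboxylic acid end groups of PLGA chains in a bulk-eroding microsphere;
the generation term is *positive* (each chain scission creates an acid end
group), which distinguishes this problem from the classical catalyst-pellet
case where the reaction consumes the diffusing species.

Assumptions inherited from this formulation:

- pseudo-first-order kinetics: the water and ester-bond concentrations are
  treated as constant and absorbed into k — valid up to roughly the maximum
  reaction time t_max (below);
- a single uniform diffusivity for all acid end groups regardless of the
  chain length they sit on (in reality only short chains are mobile, so a
  deliberately reduced effective D should be used);
- constant particle volume (no swelling), spherical symmetry, Dirichlet
  surface condition (perfectly buffered medium; c_r1 > 0 corresponds to a
  strongly acidic external medium and is mathematically supported but
  physically unusual).

## Analytical solution

Substituting v = r c turns the spherical operator into the plane Laplacian.
v is the superposition of the linearized steady state
u(r) = c_r1 sin(Φr)/sin Φ and a transient remainder expanded in the
Dirichlet eigenfunctions sin(nπr), giving

    c(r, t) = c_r1 sin(Φr)/(r sin Φ)
              + Σ_{n≥1} a_n(0) exp(−(n²π² − Φ²) α t) sin(nπr)/r,

    a_n(0) = ∫₀¹ 2 r c_t0(r) sin(nπr) dr + 2 c_r1 nπ(−1)ⁿ/(n²π² − Φ²),

which for a uniform initial value c_t0 reduces to
a_n(0) = −2c_t0(−1)ⁿ/(nπ) + 2c_r1 nπ(−1)ⁿ/(n²π² − Φ²). The Thiele modulus
Φ = √(k/α) controls the sign of every exponent: all modes decay for Φ < π,
the n = 1 mode is neutral at Φ = π (leaving the nontrivial center limit
c(0, ∞) = 2c_t0 when c_r1 = 0), and it grows for Φ > π. A steady state
exists iff n²π² − Φ² ≥ 0 for all n, i.e. Φ ≤ π. For c_r1 > 0 both the
steady part and the n = m coefficient blow up at Φ = mπ: the analytical
solution does not exist there and the finite-difference solver is the only
route (its transients remain finite at finite time).

Limiting solutions: dropping diffusion gives the reaction-dominant limit
c_rxn = c_t0 e^{kt}; dropping the reaction gives the pure-diffusion series
c_diffn. For uniform c_t0 with c_r1 = 0 the full solution factorizes
exactly as c = e^{kt} · c_diffn, so the two limits bracket it pointwise for
every Φ — a property the test suite checks directly.

The reaction-time bound t_max = ln(M_n0/M_1)/k marks complete conversion of
ester bonds to monomers under pure first-order growth (M_n0 = initial
number-average molecular weight, M_1 = mean monomer weight, both in Da);
beyond it the constant-ester assumption underlying k is void.

## Numerical choices

**Series truncation.** Adaptive by default: terms are summed in blocks of
64 and summation stops once two consecutive term bounds fall below 1e−12
relative to the running partial sum (hard cap 10 000 terms; exceeded only
as t → 0, which is short-circuited anyway). The bound uses
|sin(nπr)/r| ≤ nπ, so it is uniform over the radial grid. The factor
exp(−n²π²αt) makes convergence rapid for any t > 0. A fixed truncation
order can be requested instead (`n_terms`), which the acceptance script
uses (200 terms) for reproducibility.

**t = 0.** The series does converge to the initial profile, but only slowly
and with Gibbs oscillation at the surface when c_t0(1) ≠ c_r1 (the
transformed initial condition is discontinuous there), so t = 0 returns the
supplied initial profile directly.

**r → 0 and r = 1.** All sin(xr)/r expressions are evaluated through the
sinc identity sin(xr)/r = x·sinc(xr/π), which is finite at the center by
construction (the analytic limit substitutes nπ, resp. Φ). Radii within
1e−12 of the surface return exactly c_r1 for t > 0.

**Singularity tolerance.** |Φ − mπ| < 1e−9·max(1, Φ) with c_r1 > 0 raises a
`SingularPhiError`. With c_r1 = 0 the same Φ is perfectly regular (the
c_r1-proportional terms are defined as zero) and is evaluated normally.

**Overflow guard.** In the growth regime a series exponent above +700 (the
double-precision limit) raises an explicit `OverflowGuardError` pointing at
the t_max bound, rather than clamping or returning inf: times that large
are outside the model's validity regardless.

**Quadrature.** General initial profiles use adaptive quadrature
(`scipy.integrate.quad`) per mode to absolute tolerance 1e−10.

**Finite-difference solver.** Method of lines on a uniform grid r_i = i/N
(default N = 200) with second-order centered differences in spherical
form; the center node uses the symmetry form 6α/Δr²(c₁ − c₀) + kc₀ and the
surface node is frozen at c_r1. Time integration uses
`scipy.integrate.solve_ivp` with LSODA (rtol 1e−8, atol 1e−10) and a banded
(tridiagonal) Jacobian. LSODA was chosen over a purely explicit
Runge–Kutta method because the semi-discrete diffusion operator has
eigenvalues up to ≈ 6N²α, which stability-limits explicit steppers to
millions of steps at N = 400 while the solution itself is smooth; LSODA
integrates the same cases in milliseconds and falls back to Adams methods
when the problem is genuinely nonstiff. Explicit methods remain selectable
via the `method` argument for cross-checks at coarse grids. Measured
spatial convergence against the series solution is second order across
N ∈ {50, 100, 200, 400}, and the two solvers agree to better than 1e−3
relative over the regimes Φ/π ∈ {0.1, 0.75, 1.25}.

**Regime boundary.** `classify_regime` compares Φ to π exactly (no
tolerance band): Φ ≥ π is labelled erosion-controlled, with Φ = π flagged
as the tipping point; `steady_state_exists` separately reports that a
steady state still exists there. Near-π probing should go through
`steady_state_exists`, which applies the singularity tolerance.

## Fixtures and conventions

`make_fixtures` emits the canonical Thiele-modulus sweep panels used to
explore the regimes: the transient surfaces (Φ/π ∈ {0.1, 0.75, 1, 1.25,
5}, c_r1 = 0), the large-Φ center trajectories against t/t_max (Φ/π ∈ {1,
1.25, 1.5, 1.75, 2, 3, 5}; requires k, M_n0, M_1 to fix t_max and the
normalization (c_t0 + c_E)/c_t0 = M_n0/M_1, a relation *inferred* from the
complete-conversion condition since c_E is never specified directly), the
intermediate-Φ trajectories (Φ/π ∈ {0.25, 0.5, 0.75, 0.9, 0.99, 1}), and
the steady-state profiles for c_r1 > 0 (Φ/π ∈ {0.25, 0.5, 0.75, 0.9}).
Time grids may be given on the αt or kt axis (the conventional choice is
αt for Φ ≤ π and kt above), but profiles always store raw t so that
analytic and finite-difference outputs compare directly. CSV output is
long/tidy (`time, r, concentration`) at 17 significant digits, which
round-trips doubles bit-exactly.

## Problem sizes

The test suite and acceptance script run the series solution with adaptive
truncation (typically < 100 terms), the finite-difference solver at
N ∈ {50, …, 400}, and the regime scan over Φ ∈ (0, 5] at 1e−6 resolution
(5×10⁶ grid points, vectorized); the full suite completes in a few seconds
on one core.

## Known limitations

- Drug transport and release curves, pore-structure evolution,
  molecular-weight distribution dynamics and particle swelling are out of
  scope: the package models the autocatalyst field only.
- The single-diffusivity assumption overestimates autocatalyst mobility;
  distinguishing soluble and insoluble populations would require a
  two-field numerical model.
- k and D are constants: no temperature/pH dependence and no estimation
  from experimental data.
- The Dirichlet surface condition excludes external mass-transfer
  resistance (no Robin boundary option).
- For Φ > π the model is meaningful only up to t_max; the overflow guard
  enforces the double-precision horizon, not the physical one.
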