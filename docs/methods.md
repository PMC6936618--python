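# Methods

## Model

A dilute suspension of rigid, fore–aft symmetric, high-aspect-ratio
Brownian fibres (M13 bacteriophage: length a* = 800 nm, width b* = 6 nm,
r = a*/b* ≈ 133) is carried by pressure-driven flow along a rectangular
channel of half-depth h* and half-width W*, with h*, W* much smaller than
the channel length so the lubrication approximation applies. The axial
velocity u(y, z) then satisfies a two-dimensional elliptic balance on the
cross-section, and the fibre orientation enters the fluid stress through
the moments of the orientation distribution ψ.

Because the particles are far smaller than the channel, each point of the
cross-section carries its own homogeneous-shear orientation problem: the
distribution ψ(θ′, φ′) in the local frame (rotated about the flow axis by
β = atan2(∂u/∂z, ∂u/∂y) so the velocity gradient is along y′) satisfies

    steady:    (1/6) Λψ = Pe Υψ,          Pe = γ̇ P_G / 6 (dimensionless γ̇)
    transient: ∂ψ/∂τ = (1/6) Λψ − Pe(τ) Υψ,   τ = 6 D_r t*

with Λ the spherical Laplacian and Υ the shear advection operator. The
global Péclet number P_G = G*h*/(D_r μ) measures forcing strength against
rotary diffusion.

Assumptions inherited from this formulation: rigid particles (the M13
persistence length vastly exceeds its contour length), spatially uniform
concentration (no shear-induced migration; the translational-diffusion
migration time is ~10⁵ s, far beyond residence times), dilute one-way
hydrodynamic interactions only (n_d a*³ < 1; a warning is emitted beyond),
infinitely slender Jeffery dynamics (α₀ = 1), and no optical scattering in
the signal model.

## Spectral orientation kernel

ψ is expanded in unnormalized associated Legendre harmonics
P_n^m(cos θ′){cos, sin}(mφ′) with n, m even (antipodal symmetry) and
A⁰₀₀ = 1/(4π) pinned by normalization. Λ is diagonal (−n(n+1)); Υ couples
(n, m) to (q, p) with |q−n| ≤ 2, |p−m| ≤ 2 via coefficients a^{m,p}_{n,q}.
Rather than transcribing printed coefficient tables, the coefficients are
generated by applying Υ analytically to each basis function and projecting
on a Gauss–Legendre × uniform-φ grid sized so every integrand (a polynomial
in cos θ′ times a trigonometric polynomial) is integrated exactly; entries
below 1e−12 are dropped as structural zeros. Two independent
reconstructions (cosine-source and sine-source projections; an exact
rational symbolic construction in the test suite) agree to 1e−10.

The steady system is a dense linear solve over all retained modes (~40
unknowns at N = 10). Transients use Heun's second-order scheme. The shear
coupling has near-imaginary eigenvalues of magnitude ≈ 5.5 |Pe| with weak
damping, so the per-flow-step orientation update is sub-stepped with
h ≤ 2/ρ^{4/3} (ρ the cached spectral-radius bound) to stay inside Heun's
stability region; normalization is conserved algebraically because Υ is a
divergence on the sphere (no coupling into the constant mode).

Truncation order N = 10 (default) converges S to better than 1e−3 for
Pe ≲ 6 — the regime occupied by the standard channel runs. At Pe ~ 20 the
N = 10 truncation error in S is ~1e−2 (the angular-grid finite-difference
oracle and N ≥ 14 solves agree on S = 0.6545, N = 10 gives 0.6641); N = 8
is used for the coarse oscillatory presets where this bias is within the
reported tolerances.

Moments are linear functionals of the coefficients, precomputed once per
basis by exact quadrature and applied as small matrix products; lab-frame
tensors follow by rotating about the flow axis (p_x is invariant, the
(y, z) blocks rotate as 2-tensors).

## Flow solvers

Steady: the anisotropic PDE is discretized in conservative flux form with
second-order central differences (half-node arithmetic averaging of c_yy,
c_zz; centred mixed c_yz fluxes; one-sided second-order gradients at
walls), Dirichlet u = 0 on the walls, solved by sparse LU. The coupled
problem iterates: velocity → (Pe, β) fields → per-node steady orientation
solves → coefficient/source fields → re-solve, with optional
under-relaxation (ω = 1 default, 0.5 fallback), until the relative max-norm
velocity change is below 1e−6 (≤ 50 iterations; 3 suffice at standard
parameters because the suspension correction to u is O(10⁻²·S) ≈ 10⁻³–10⁻²).
Per-node solves are pure functions of (Pe, β); any evaluation order or
parallel schedule gives identical fields.

Oscillatory: the real pressure-gradient forcing is P′(t) = cos(t + π/2) =
−sin t (the complex-exponential drive cannot propagate through the
nonlinear orientation coupling; the quarter-period phase shift starts the
system from rest). Peaceman–Rachford ADI advances u with implicit
tridiagonal solves alternately in y and z; mixed fluxes and the
particle-stress divergence are explicit in both half-steps, with forcing
evaluated at the half-step midpoints. Orientation states advance over
dτ = (6 D_r/ω*) dt using the velocity lagged by one step (first-order
operator splitting). Each node's shear frame is fixed over the run at the
steady-profile gradient direction and the instantaneous shear is projected
onto it, giving a signed Pe(t); the discarded perpendicular shear carries
≤ 0.2% of the shear energy up to α² ≈ 4, so this loses nothing measurable
while avoiding rotation of the harmonic basis in time. Defaults: 1200
steps per period, 3 periods, statistics on the final period (the series is
periodic to < 1% by period 3); the reported oscillatory orientation
parameter is the final-period maximum of the spatially averaged S, and LD
uses the half-period time-averaged S field.

## Material parameters

D_r defaults to the slender-rod formula 3 k_B T (ln 2r − 1/2)/(π μ a*³)
(40.65 s⁻¹ at standard inputs) and may be overridden by a measured value.
The particle volume defaults to the prolate-spheroid value (π/6) a* b*²;
with the standard number density this reproduces the tabulated volume
fraction Φ = 1.11e−5 exactly, so the spheroid default is retained and any
other volume must be supplied explicitly. The constitutive constants use
the slender-fibre limits α₂ = r²/(2(ln 2r − 3/2)), α₃ = (6 ln 2r − 11)/r²,
α₄ = 1, α₅ = 0, α_r = 3r²/(ln 2r − 1/2): these are the r → ∞ forms of the
exact ellipsoidal-integral expressions, chosen because the orientation
dynamics already take the same limit (α₀ = 1) and because at r ≈ 133 the
finite-r corrections are O(1/ln 2r) on terms that perturb the flow by at
most O(10⁻²). The fundamental ellipsoidal integrals are implemented by
adaptive quadrature and validated against their closed forms, pinning the
asymptotics. Physical constants (k_B, N_A) are config keys carrying the
values tabulated with the parameter set, so derived groups match the
published table; both can be overridden.

## Numerical choices and degenerate inputs

- Grids are vertex-centred including walls; defaults Y = 150, Z = 120 (the
  resolution at which the velocity and S fields are grid-converged), with
  coarse presets 60×48 (steady) and 40×32 (oscillatory) used by tests and
  the acceptance script. Observed spatial order ≈ 2.0 against the analytic
  duct series.
- Zero-shear nodes (channel centre, corners) take Pe = 0, β = 0: the local
  distribution is isotropic so the frame is immaterial.
- ψ non-negativity is not enforced; spectral truncation admits small
  negative excursions. Only normalization and symmetry are structural.
- Ellipticity c_yy c_zz − c_yz² > 0 is checked at every assembly and holds
  for all admissible moments up to Φ = 1e−2 (randomized sweep in the test
  suite).
- G* = 0 short-circuits to exact isotropy (S ≡ 0, LD = 0).
- All pipelines are deterministic; the config seed exists only for the
  Monte-Carlo test oracles.

## Validation oracles

Independent of the production code path: the classical double-series duct
solution and the duct Womersley series (Φ = 0 limits); a conservative
finite-difference solution of the angular Fokker–Planck equation on a
pole-staggered 200×400 (θ, φ) grid; 10⁷-sample Monte-Carlo moment
integration of the reconstructed ψ; and an exact rational symbolic
construction of the coupling table. `ductld validate` runs a quick version
of this suite.

## Known limitations

- The oscillatory orientation coupling is first-order in time (lagged
  velocity); halving the step changes final-period statistics by < 0.5% at
  the default resolution.
- At strong local shear (Pe ≳ 20) the default N = 10 truncation biases S
  high by ~1e−2; raise N for single-point studies at extreme Pe.
- The dilute constitutive law is extrapolated above n_d a*³ = 1 (a warning
  is emitted); particle flexibility, concentration inhomogeneity, active
  stresses and optical scattering are outside the model.
- The uniaxial (membrane) orientation formula is provided only for
  comparison; it over-predicts alignment wherever alignment is appreciable
  but can under-predict slightly in the near-isotropic mid-channel band.
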