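# Methods

This note documents the models, numerical choices and deliberate design
decisions behind `rbc_oxyshear`, in the order data flows through the package.

## Ektacytometry and curve parameterization

The elongation index EI = (a − b)/(a + b) of the elliptical diffraction
pattern is dimensionless and lies in (−1, 1); negative values are physical
artifacts of fragmenting ghost membranes, not elongation.  Deformability
curves live on the canonical ten-level shear-stress ladder
{0.3, 0.53, 0.94, 1.65, 2.91, 5.15, 9.09, 16.04, 28.32, 50} Pa.

The Lineweaver–Burke parameterization assumes the saturating hyperbola
EI(SS) = EI_max·SS/(SS_1/2 + SS) and fits its linearization 1/EI = 
(SS_1/2/EI_max)·(1/SS) + 1/EI_max by unweighted ordinary least squares
(weights are an option, default off: the measurement protocol reports no
weighting).  EI_max = 1/intercept, SS_1/2 = slope/intercept, and the stored
`ratio` is exactly `ss_half / ei_max`.  The linearization is exact on
noiseless hyperbolas, which the tests exploit as an oracle.  Points with
EI ≤ 0 are excluded with a warning and counted: 1/EI is meaningless there,
and only intact-cell curves are hyperbola-like.  All ten levels enter the fit
by default (the protocol does not single out a subset); fewer than three
usable points or a non-positive intercept raise typed errors rather than
returning nonsense.

Protocol summaries average replicates within subject before computing the
cross-subject standard error (n − 1 denominator), matching a design of 10
subjects with two replicate runs; a single subject reports SE = 0 by
convention.

## Two-term exponential calibration

The bridge between discrete measurements and a continuous stress field is
EI(SS) = c1·e^(r1·SS) − c2·e^(−r2·SS), with c1, c2 dimensionless in (0, 1]
and rates r1 ∈ [0, 0.1], r2 ∈ (0, 5] Pa⁻¹.  With all coefficients positive
the function is strictly increasing, its zero-stress value is c1 − c2, and
the small r1 gives a slow exponential drift above the saturating rise.  Two
published presets are built in (oxygenated `eq1_oxygenated`, deoxygenated
`eq2_deoxygenated`); the deoxygenated preset lies strictly above the
oxygenated one on the whole measured range, which propagates to every mapped
field.

Fitting uses bounded trust-region least squares with 8 deterministic
restarts from a seeded Latin hypercube over the bounds: two-exponential
models have local minima, and the bounds encode the physical EI range and
the magnitudes of the printed coefficients.  R² is defined on untransformed
EI residuals (1 − SS_res/SS_tot), matching a single reported goodness of fit
for a nonlinear fit; it is computed against the mean curve per condition
(pooled-point R² is a config choice away, but the mean curve is the default
because the calibration is meant to represent the condition, not one run).
Because the bounds force monotone fits, data the model cannot represent
(ghost curves) are flagged through goodness of fit (`quality_ok_` False
below R² = 0.9) and the always-run numerical monotonicity check, rather
than through a non-monotone fitted function.

Inversion of the calibration uses bracketed Brent root finding on
[0, 100] Pa (the monotone model makes the root unique); the round trip
|evaluate(invert(ei)) − ei| holds to 1e-10.

## Casson rheology

Apparent viscosity μ(γ̇) = (√(τ_y/γ̇) + √μ_c)² for γ̇ > 0, with the nominal
blood viscosity 0.0035 Pa·s as the γ̇ ≤ 0 fallback.  The infinite-shear
viscosity is μ_c = μ0·(1 − Hct)^(−1/2) — with plasma viscosity
μ0 = 1.45e-3 Pa·s and Hct = 0.4 this is 1.872e-3 Pa·s, within 1% of the
1.886e-3 Pa·s minimum a full 3-D simulation reports.  (The underlying N∞
formula is kept in the dimensionally consistent square-root form
N∞ = √μ0·(1 − Hct)^(−1/4), which this agreement supports.)

Two yield-stress parameterizations are kept because the source formula for
μ∞ is typographically ambiguous:

* `literal` (default): μ∞ = 0.625·Hct, so τ_y = 0.0625 Pa at Hct 0.4;
* `calibrated`: μ∞ = √(0.1·(0.625·Hct)³), so τ_y = 1.56e-3 Pa at Hct 0.4 —
  under this law the default viscosity cap 2.072e-2 Pa·s (the reported field
  maximum) is reached at γ̇ ≈ 0.15 s⁻¹, a plausible near-stagnation rate,
  which is why `calibrated` is recommended for reproducing field extrema.

The cap bounds stiffness near stagnation and is configurable or disableable.
Note one asymptotic subtlety: at γ̇ = 10⁶ s⁻¹ the literal preset's viscosity
is still 1.16% above μ_c (its yield stress is 40× larger than the calibrated
one), so the "within 1% at 10⁶ s⁻¹" asymptote statement holds for the
calibrated preset; the literal preset reaches it by 10⁸ s⁻¹.

The scalar shear rate is γ̇ = √(2 D:D) with D the symmetric velocity-gradient
part; it is rotation-invariant, which the tests check with random rotations.

## Flow solver

The solver computes fully developed unidirectional flow: u varies across the
lumen (and in time), v ≡ 0, and the pressure is linear in x.  Continuity and
the mass-conservation contract then hold exactly, no-slip is imposed exactly
at wall nodes, and the centerline pressure decreases monotonically
downstream.  The cross-stream momentum balance
ρ·∂u/∂t = G(t) + ∇·(μ(γ̇)∇u) is discretized with a second-order
finite-volume scheme on nodes (tube version in cylindrical form with a
symmetry volume at the axis), and the axial gradient G(t) is determined at
every instant by superposition so the lumen-mean velocity equals the imposed
inlet velocity (flow-rate-driven forcing).  Verified behavior: plane/axisymmetric
Poiseuille ratios to < 1% in the Newtonian limit, < 0.01% L2 velocity error
against the semi-analytic Casson tube oracle at 128 radial cells, and clean
second-order grid convergence (error ratio ≈ 4 per spacing halving).

The tube oracle itself uses the exact momentum balance τ(r) = τ_w·r/R,
inverts the (optionally capped) Casson law for γ̇(r) — so oracle and solver
share one constitutive relation — and integrates inward from the wall.  With
the cap disabled it reproduces the classic plug flow (γ̇ = 0, constant u for
τ < τ_y) and the no-flow condition at τ_w ≤ τ_y.

Pulsatile runs use the sinusoid v(t) = (v_min+v_max)/2 +
(v_max−v_min)/2·sin(2πt/T) (defaults 0.1/0.5 m/s, T = 0.5 s; the phase is
fixed at the ascending mean crossing for determinism), backward-Euler time
stepping at advective CFL 0.45 (an explicit dt violating CFL 0.5 is rejected
up front), and Picard treatment of the viscosity with under-relaxation 0.7.
Because the viscous time scale of a ~6 mm lumen (h²/ν ≈ 5 s) spans many
pulse periods, the time-periodic state is computed directly instead of
waiting for transients: within each Picard sweep the affine one-period map
of the implicit scheme is propagated (monodromy matrix over the free nodes)
and its cyclic fixed point solved exactly.  Sweeps repeat until the
period-to-period velocity change falls below 1e-7·v_max — four orders below
the 1e-3·v_max periodicity contract.  Fields are stored at 20 equispaced
phases by default.

Wall shear stress is μ_wall·|∂u/∂n| from a three-point one-sided
second-order difference at the wall (exact for parabolic profiles).  The
gravity term is dropped (horizontal vessel, single outlet gauge pressure
13.332 kPa — it would only shift the hydrostatic datum), and blood density
defaults to 1060 kg/m³.

Default problem sizes — channel of half-height 3.15 mm (6.3 mm lumen,
matching a main carotid inlet) and length 60 mm on a 64×256 grid, ≈ 2400
implicit steps per pulse period — solve a full periodic pulsatile problem in
well under a minute on one core; these sizes are the package's desk-scale
operating point.  The 3-D patient-specific carotid bifurcation, tetrahedral
meshing and commercial-solver settings are out of scope; the straight
channel/tube is the quantitative stand-in, so 3-D field extrema are treated
as plausibility anchors, not reproduction targets.

## EI mapping

Interior cells are mapped through EI = cal(τ) with τ = μ·γ̇ the local
shear-stress magnitude (the whole lumen is painted, not just walls); the map
is a deterministic, monotone, pure function of (τ field, calibration).
Stresses below 0.3 Pa are extrapolated with the fitted function rather than
clamped — the mapped minimum legitimately falls below the lowest measurable
EI — and cells outside the fit domain are counted in the field's metadata.
The wall and center bands default to 10% of the lumen half-width (a
reporting convention, configurable), and the wall/center EI ratio is
reported per phase because the contrast varies strongly over the cycle: on
the default pulsatile channel the per-phase ratios span ≈ 1–10 and reach the
5–10× band during the accelerating phases.  The EI map is close to a
negative image of the viscosity map (Spearman ρ ≈ −0.999 on a steady
channel): higher shear means lower viscosity and higher elongation.

## Synthetic data generator

The generator emulates the measurement design only: 10 subjects × 2
replicates × {oxygenated, deoxygenated} × {before, after 5 Pa × 300 s
conditioning} on the canonical ladder, EI = truth(ss) + conditioning shift +
subject intercept + noise.  Condition truths default to the built-in presets;
the conditioning effect (+0.01 EI) applies only at SS ≤ 1.65 Pa, the levels
where conditioning measurably improves deformability.  Noise is additive
Gaussian — σ = 0.005 within-measurement, chosen to make standard errors of
~0.005–0.01 at n = 10 plausible, and σ = 0.01 between subjects; both are
placeholders for unpublished variance components, not estimates of any real
dataset.  Ghost curves rise hyperbolically to ≈ 0.3 by ~3 Pa and then a
fragmentation sigmoid drags them below zero above 5.15 Pa; they exist to
exercise exclusion and misfit error paths.  What passing recovery tests
show, therefore, is that the *pipeline* is unbiased and stable under this
idealized error structure — they do not validate the error structure of real
LORRCA data (drift, heteroscedasticity, outliers are not modeled).

## Determinism and configuration

All randomness flows from explicit integer seeds (`numpy.random.default_rng`);
identical configuration and seed give byte-identical reports and VTK output.
Units are SI throughout (Pa, m, s, Pa·s), with units embedded in CSV/JSON
key names.  Run configuration is YAML; the main keys are `seed`, `synth.*`,
`calibration.{use_presets,n_starts}`, `flow.geometry.{kind,half_height,
radius,length}`, `flow.inlet.{kind,v_min,v_max,period,velocity}`,
`flow.rheology.{hct,mu0_pa_s,preset,mu_cap_pa_s,mu_fallback_pa_s}`,
`flow.grid.{nx,ny}`, `flow.{dt_s,n_periods,n_store,outlet_gauge_pressure_pa,
rho_kg_m3}`, and `output.{fields_dir,report}`.

## Known limitations

* No 2-D/3-D bifurcation solver: stagnation-point and sinus-recirculation
  physics are represented only through the stress→EI calibration, not
  simulated.
* Rigid walls, no fluid–structure interaction; laminar only.
* The Casson cap replaces the true yield-stress plug with slow Newtonian
  creep below the crossover stress; disable the cap to recover exact plugs
  (the oracle supports both).
* The calibration is an empirical bridge: extrapolation above 50 Pa inherits
  the exponential drift term with no data behind it (inversion is therefore
  bounded at 100 Pa by default).
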