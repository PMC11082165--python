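# Methods

## The droplet micro-reactor model

A spherical condensate of radius R sits in an infinite quiescent bath.
Urease, partitioned entirely into the dense phase, hydrolyses urea:
CO(NH₂)₂ + H₂O → 2 NH₃ + CO₂ with Michaelis–Menten kinetics (k_cat, K_m),
and the products exchange protons with water and the phosphate buffer
through four fast reactions (NH₄⁺/NH₃, CO₂/HCO₃⁻, H₂O/OH⁻+H⁺,
H₂PO₄⁻/HPO₄²⁻).  CO₃²⁻ and PO₄³⁻ are omitted: they are negligible at the
pH values the reactor reaches, and the code deliberately offers no switch
to add them.

At steady state, with advection neglected (the droplet-scale transport
Péclet number VR/D is far below one), the nine species concentrations
c₁..c₉ obey diffusion equations whose proton-exchange source terms are
eliminated by forming four conserved flux combinations (total nitrogen
with the 2× urea contribution, total carbon with the urea contribution,
a charge-like proton combination, and total phosphate).  The bimolecular
rate constants of the fast reactions drop out; only their ratios — the
acid dissociation constants — remain, entering through pointwise
equilibrium closures.  The independent fields are therefore

  u = (c_urea, N = c_NH3 + c_NH4, C = c_CO2 + c_HCO3, P = c_HPO4 + c_H2PO4, c_H),

and every species is reconstructed exactly from u by Henderson–Hasselbalch
splits plus c_OH = K_w / c_H.

**Spatial modifiers.**  The enzyme profile is c_e(r) = c_e^d S(r) with the
smooth step S(r) = ½(1 − tanh(s(r−R)/R)), sharpness s = 100.  Each
diffusivity is interpolated between its dense- and dilute-phase values with
the *same* step, D_i(r) = D_i^dilute + (D_i^dense − D_i^dilute) S(r).
Phase values follow obstruction theory, D_i = D_i^w (η/η^w)^{−3/5}, with
η^w = 1 mPa s: the diffusing solutes are far smaller than the
macromolecules that set the bulk viscosity, so Stokes–Einstein would
grossly over-suppress them.  Small molecules do not partition
(concentrations are continuous at the interface).

**Units.**  Everything internal is SI (mol/m³, m, s, Pa s; mol/m³ is
numerically mM).  pKa values are defined on the molar scale and converted;
K_w is a concentration *product* (10⁻¹⁴ M² → 10⁻⁸ (mol/m³)²) while the
other constants are ratio-scale (10^{−pKa} × 10³ mol/m³).  Temperature is
fixed at 298.15 K wherever kT appears, overridable through
`PhysicalConstants`.

### Default parameters

Shipped in `src/dialytaxis/data/default_params.yaml`:

| quantity | value | note |
|---|---|---|
| D_i^w | 1.38, 1.50, 1.96, 1.67, 1.19, 9.31, 5.27, 0.76, 0.96 ×10⁻⁹ m²/s | urea, NH₃, NH₄⁺, CO₂, HCO₃⁻, H⁺, OH⁻, HPO₄²⁻, H₂PO₄⁻ in water |
| pKa₂, pKa₃, pK_w, pKa₅ | 9.25, 6.35, 14, 7.21 | molar scale |
| K_m | 23 mM | urea–urease |
| k_cat | 4400 s⁻¹ | reference activity; an aged-enzyme batch can sit an order of magnitude lower |
| c_e^d | 1 µM | dense-phase enzyme; with infinite partitioning c_e^d = c_e/φ_d (1.2 µM overall at φ_d = 3% gives 40 µM) |
| η_dense, η_dilute | 0.8 Pa s, 24 mPa s | measured condensate range is 0.1–1 Pa s |
| far field | pH 6.8, 100 mM urea, 100 mM phosphate | products absent at infinity |

The far-field state is constructed, not free: H⁺ from the pH, OH⁻ from the
water product, and the phosphate total split by its pKa; construction is
validated against every closure to 10⁻⁹ relative.

## Numerical solution

The five equations are discretized with a conservative finite-volume
scheme on a stretched radial grid: a uniform band across the droplet edge
with spacing ≤ R/(2s) for |r − R| ≤ 0.2R (the step has width ~R/s), and
geometric stretching toward the center and the far boundary.  Symmetry at
r = 0 is imposed naturally through the vanishing inner-face area; the far
field is a Dirichlet condition at r_max = 50R by default.  Because no
truncation rule is canonical, insensitivity is tested: moving r_max from
50R to 100R changes the center pH by < 10⁻³, as does doubling the node
count (260 → 520) at the reference operating point.

The nonlinear system is solved by damped Newton iteration on
(c₁, N, C, P, log c_H) — the log transform keeps H⁺ positive across the
2–3 decades it traverses, totals are clipped at zero inside the line
search, and the log-H⁺ step is trust-region-capped at 2 units.  The
Jacobian is assembled by colored finite differences (the stencil couples
three neighbouring nodes, so 15 residual evaluations suffice) and factored
sparsely.  Initialization is the uniform far-field state; if the direct
solve stalls (very large Da), k_cat is ramped geometrically over 8
continuation steps.  Convergence is an RMS scaled residual below 10⁻⁸.
A typical solve takes tens of milliseconds at 260 nodes.

Correctness is established three independent ways in the test suite:
(i) a collocation discretization of the same reduced system
(`scipy.integrate.solve_bvp`) agrees with the finite-volume center pH to
10⁻³ at a moderately reacting radius (the two agree to ~10⁻⁵ at tight
tolerances); (ii) with equal constant diffusivities and saturating
substrate, every conserved total matches the closed-form uniform-source
solution (excess ∝ qR³/3Dr) to 0.5% out to 10R (this configuration uses
r_max = 5000R so the infinite-domain form applies); (iii) discrete
conservation — the four combined shell fluxes vanish to rounding, urea
influx balances the volume-integrated sink to 1%, and ammonia export is
twice the urea consumption.

## Damköhler analysis

Inside the droplet the urea equation nondimensionalizes to
∇̃²c̃ = Da c̃/(1 + c̃) with Da = k_cat c_e^d R² / (D₁ K_m).  The package
reports Da with the **dense-phase** urea diffusivity
(D₁ = 1.38×10⁻⁹/(800)^{0.6} ≈ 2.5×10⁻¹¹ m²/s at η_dense = 0.8 Pa s), the
phase in which the reduction is derived; `dense_phase_D1` makes the
convention explicit and any other D₁ can be passed for sensitivity checks
(the dilute-phase convention multiplies all Da values by ≈ 8.2).

A radius sweep at the reference chemistry maps Da to the steady pH
increase at the drop center and edge.  `threshold_da` interpolates the
crossing of a 0.1-unit increase linearly in (log Da, ΔpH).  Under the
dense-phase convention the acceptance script computes the center-pH
crossing at Da* ≈ 0.59 and the edge-pH crossing near Da ≈ 3; the two
curves bracket unity, so "a noticeable pH rise requires Da of order one"
is the regime statement this model supports.  The center pH eventually
stalls: ammonia becomes the dominant buffer once the center approaches its
pKa (the solver gives center pH 8.91 at R = 150 µm, Da ≈ 172).

## Motility predictors

* V_m = |Δγ|/6η for an idealized Marangoni swimmer in an unbounded linear
  tension gradient; confinement and finite viscosity-ratio corrections are
  deliberately not applied.  Direction is reported separately: velocity is
  positive along +x of the supplied gradient, and drops swim *down* the
  tension gradient (sign(U) = −sign(∂γ/∂x)).
* Δγ = 2R (dγ/dpH)(dpH/dx), signed and bilinear; no |Δγ| ≤ 2R|∇γ| capping.
* γ = prefactor (φ_m/φ_c − 1)^ν with the mean-field ν = 3/2; a mixed state
  (φ_m < φ_c) returns γ = 0 with a flag.  The dialytaxis velocity scale
  U ∼ (R/η)(∂φ_c/∂c)(∂c/∂x) keeps its model prefactor at 1 and is labelled
  a scale, not a calibrated speed; positive means swimming up the solute
  gradient, the dissolving direction for ∂φ_c/∂c > 0.
* Pe = (η_dilute/η) πR²Δγ/kT.  `peclet_bounds` exploits monotonicity in
  every argument, evaluating only the two extreme corners of the parameter
  box (viscosity contrast 10–100, γ 0.1–100 µN/m, R 0.5–10 µm, Δγ = 0.1γ),
  giving 1.9×10⁻² to 7.6×10⁴.

## Measurement estimators

**Tracer diffusivity.**  The covariance-based estimator
D = ⟨Δx²⟩/2Δt + ⟨Δx_n Δx_{n+1}⟩/Δt − (3/2)⟨Δx_{n+1} Δx_{n−1}⟩/Δt pools all
displacement moments over tracks and both axes (per-track averaging is an
option; the two differ at unequal track lengths).  The combination cancels
a constant drift exactly — straight-line tracks give ½ + 1 − 3/2 = 0 — and
static localization noise cancels between the lag-0 and lag-1 terms, which
is verified by a noise-injection test against the naive MSD estimator
(biased by σ²/Δt, and by v²Δt/2 per axis under drift).  Tracks need ≥ 4
points; shorter ones are excluded and counted.  The standard error is the
scatter of per-track estimates; a negative D (possible in noise) is
returned as-is with a flag.  Viscosity follows from η = kT/(6πaD) with the
a = 0.1 µm tracer and the 20% measurement-convention uncertainty.

**Sedimentation.**  Unweighted least squares of v = A d² through the
origin (the Stokes form has no intercept), Δρ = 18 η_dilute A / g, with
the fit error propagated from the residuals.  Requires ≥ 3 drops spanning
≥ 2× in diameter; a negative A is flagged rather than hidden.

**Sessile-drop shapes.**  The axisymmetric capillary-statics profile is
integrated in arc length from the apex: x′ = cos φ, z′ = sin φ,
φ′ = 2/b + z/ℓ_c² − sin φ/x, with the apex limit φ′ → 1/b.  As ℓ_c → ∞
this reduces to a sphere of radius b (verified to 10⁻⁶ relative at Bond
number 10⁻⁸); for b ≫ ℓ_c gravity flattens the drop.  `fit_contour` runs
nonlinear least squares over (log ℓ_c, log b, apex position, axis tilt),
measuring exact point-to-segment distances to a 250-vertex profile
polyline (nearest-vertex distances alone bias ℓ_c at the 1% level).  The
reported δℓ_c is the 10% measurement convention unless the fit covariance
is larger.  γ = Δρ g ℓ_c² and
(δγ/γ)² = (δΔρ/Δρ)² + 2(δℓ_c/ℓ_c)² hold as exact identities.

**Ratiometric pH imaging.**  Calibration fits a cubic pH(ratio) to
measured (pH, I₄₈₈/I₄₀₅) pairs and records the residual RMS, the validity
interval, and a monotonicity flag (non-monotone data warn but still fit).
Conversion subtracts the sensor dark level, flat-field divides both
channels, forms the ratio, and applies the cubic; non-positive
denominators (dye-free droplet interiors) and out-of-range ratios are
masked.  The gradient around a droplet is a single line fit through the 15
valid samples nearest each edge, outside the drop; chamber profiles are
first averaged across the image width.  One-sided fits (used for the
radial profile of an isolated active drop) are supported.

**Speed statistic.**  V_m is the 0.95 quantile of recorded speed
magnitudes (linearly interpolated empirical CDF, ≥ 20 samples), so
tracking-noise outliers above the 95th percentile cannot move it.

**Concentrations.**  Beer–Lambert per dilution, averaged over replicates,
negative absorbances excluded with a warning.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of a `SyntheticSpec` (seed + parameters) and
echo their ground truth into metadata; tests consume only the data
channel.  Identical specs give bitwise-identical output.

* Brownian tracks: independent Gaussian increments (variance 2DΔt) plus
  constant drift and optional additive localization noise.
* Internal circulation: the classical closed-streamline vortex of a drop
  driven along its axis, u_x = A xz/R², u_z = A(1 − (2x² + z²)/R²) inside
  r < R — speed maxima at the center and edge equator, no flow through the
  boundary.  Advection uses Euler–Maruyama substeps capped at R/100
  displacement, with radial reflection of diffusive excursions.  Exported
  speed samples come from particles redrawn uniformly over the drop each
  frame, emulating tracers crossing a thin imaging slab; the amplitude A
  is set so that the 95th-percentile speed of that ideal distribution
  equals the requested V_m — i.e. the generator is parameterized by the
  same statistic the velocimetry reports (the pointwise field maximum is
  ≈ 5% above V_m).  The calibration constant is a deterministic quadrature
  over a disk lattice, not a fitted quantity.
* Sedimentation: Stokes-form velocities with multiplicative Gaussian
  noise.
* Drop silhouettes: the integrated profile mirrored about the apex axis
  with Gaussian noise along the local normal; defaults (400 points per
  side over a 160° turning angle) represent a millimetric non-wetting drop
  imaged at a few µm per pixel.
* Ratiometric images: a uniform reference channel and a signal channel
  carrying a single-pKa sigmoidal dye response (midpoint 7.3), both
  multiplied by a parabolic vignette, offset by the sensor dark level, and
  perturbed by Gaussian noise; droplet interiors carry no dye.  Synthetic
  calibration solutions span pH 6.8–8.4, bracketing the ~1-unit range the
  synthetic profiles traverse — calibration must cover the measurement
  range for the cubic inverse to be faithful, exactly as in the real
  protocol; deep into the sigmoid's saturated tail no calibration could
  resolve 0.05 pH at 2% intensity noise.

None of this emulates particle detection or linking, dye photophysics,
camera noise beyond offset + vignette + Gaussian, or hydrodynamic
interactions between droplets — so passing tests validate the estimators
and the model chain, not image processing on real micrographs.

## End-to-end recipes

`run_speed_comparison_recipe` draws an ensemble of droplets (R 15–40 µm, η
0.1–0.6 Pa s, pH gradients 2–8 ×10³ pH/m with random sign, tension–pH
slope −17 µN/m per pH unit), generates a self-consistent measurement set
for each (ratiometric imaging of the local pH profile and
internal-circulation velocimetry at the ground-truth V_m), and compares
the measured 95th-percentile speed with the prediction from the *measured*
gradient.  The through-origin regression slope of observed on predicted
speed is the headline number (1.01 at the default 30-droplet setting).
`run_active_droplet_recipe` chains solver → one-sided surface pH slope →
Δγ → V_m per radius.  Both emit a provenance block (config SHA-256,
package version, seed) and are deterministic given their config.

## Problem sizes

Defaults used throughout tests and the acceptance script: 260 radial nodes
(520 in the refinement check), 14-radius sweeps for the Damköhler
threshold, 200 tracks × 100 steps for microrheology, 50 sedimenting drops,
400 contour points per side, 256 × 160 ratiometric images, 150 tracers ×
150 frames for velocimetry, 25–30 droplets in the end-to-end recipe.  The
full suite runs in a few minutes on one CPU.

## Known limitations

* Purely Fickian transport: no activity coefficients, ionic-strength
  corrections, or electromigration; no advective coupling back onto the
  concentration fields; strictly steady state and spherical.
* The interior-flow generator is a parametric stand-in with the stated
  contract (confinement, maxima at center and edge), not a solved
  hydrodynamic field for a specific boundary forcing.
* Dialytaxis velocity outputs are scales with unit prefactor, not
  calibrated speeds.
* The Damköhler threshold depends on the D₁ convention (factor ≈ 8.2
  between dense- and dilute-phase choices); the package pins the
  dense-phase convention and exposes the alternative.
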