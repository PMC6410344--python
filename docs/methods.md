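# Methods

## Scope and architecture

`nanotherm` chains four physical models that are usually run in separate
tools: (i) Mie/Gans absorption of plasmonic nanoparticles, (ii) nanoparticle
diffusion and Pennes bioheat transfer in a spherical tumor phantom, (iii)
three-state hyperthermic cell-death kinetics, and (iv) exponential tumor
growth across a multi-session treatment schedule. Each stage is an importable
module with explicit units; the `workflow` module wires them together from a
YAML config. The electromagnetic near-field problem (antenna or finite-element
scattered-field) is deliberately out of scope: spheres and shells are solved
analytically, and microwave-like heating is represented by a user-supplied
volumetric source in the bioheat stage.

## Optical constants

Dielectric data ship as CSV tables (`wavelength_nm,n,k`, 400–1100 nm) loaded
at first use. Gold is the Rakić et al. (1998) Lorentz–Drude analytic model
evaluated on a 1 nm grid — a standard tabulation that avoids any network
dependency; silica is the Malitson Sellmeier dispersion; water is fixed at
n = 1.33; titania at n = 2.49. Interpolation is linear in n and k separately,
then squared into ε, so a constant-index table is reproduced exactly. All
dielectric functions use the physics convention ε = ε₁ + iε₂ with ε₂ ≥ 0;
tabulated (n, k) pairs, which follow the engineering convention n′ − j n″, are
converted at exactly one point (`materials.bulk_dielectric`) to avoid
double-negation bugs.

The choice of gold dataset moves plasmon peaks by a few nanometres. With
Rakić Lorentz–Drude the 40 nm sphere in water peaks at 525 nm; with a
Johnson–Christy-type tabulation at 523–527 nm. Experimental reports for
~40 nm gold colloids cluster near 533–535 nm. Values near 540 nm reported
from finite-element solvers of the same geometry are, in our assessment,
discretization artifacts; no standard dataset reproduces them under exact Mie
theory (the package's Mie code agrees with an independent
logarithmic-derivative implementation to machine precision, so the
discrepancy is not numerical).

The surface-scattering (Kreibig) correction replaces the bulk Drude damping
rate v_F/L∞ with v_F/L∞ + A·v_F/L_eff. Defaults for gold:
ωp = 1.37×10¹⁶ rad/s, v_F = 1.4×10⁶ m/s, L∞ = 42 nm, A = 1. L_eff defaults to
the particle radius for solid spheres and the layer thickness for shells, and
the correction is applied only to materials with Drude constants on file
(gold); dielectric layers pass through unchanged.

## Mie and Gans numerics

The shell coefficients aₙ, bₙ (with core auxiliaries Aₙ, Bₙ) are evaluated
directly from Riccati–Bessel functions at complex argument via scipy's
spherical Bessel routines; the series is truncated at the Wiscombe order
nmax = ⌈x + 4x^{1/3} + 2⌉. This direct evaluation is validated in the test
suite against an independent Bohren–Huffman-style algorithm (downward
recurrence of the logarithmic derivative) to 10⁻⁶ relative over the full size
range used (x ≲ 16, |mx| ≲ 50), and the truncation is checked to be converged
to 10⁻⁸. Degenerate limits (core = shell material; vanishing core) reproduce
the solid sphere, and Qabs ≤ Qext always.

Spectra are scanned on user grids and the peak is the grid argmax with no
sub-grid interpolation, matching ±1 nm reporting. The spheroid (Gans) cross
section is quasi-static with no retardation correction: quantitative only for
particles well below the wavelength, and used here for the qualitative
red-shift-with-aspect-ratio behaviour. At axis ratio 1 it reduces exactly to
the Rayleigh dipole absorption (this identity is a test). Depolarization
factors switch to a series expansion near the sphere limit (e² < 0.0225)
where the closed form loses precision to cancellation.

The size-scaling fit σ_abs(d) = α d^p is, by default, a nonlinear least-squares
fit on the linear scale. Over 10–1000 nm the data span five decades, so this
objective is dominated by the largest particles and lands at p ≈ 1.47 — the
conventional "order 1.5" result for saturating absorption. A uniform log–log
fit of the same points weights the small-particle d³ regime equally and gives
p ≈ 1.99; both are available (`space="linear" | "log"`), and the exponent one
should quote depends on which regime matters for the application.

## Bioheat solver

Geometry is a sphere of tissue (default radius 6 mm) with a tumor core
(default 3 mm, i.e. the 113 mm³ reference volume) and one healthy tissue
outside, on a uniform radial grid (default 241 nodes, ≥ 50 enforced).
Discretization is a conservative finite-volume scheme with harmonic-mean face
conductivities (exact for the piecewise-constant tumor/healthy contrast),
symmetry at r = 0, and either a Dirichlet (T = T_b, c = 0) or sealed outer
boundary. Time stepping is backward Euler (unconditionally stable), default
Δt = 0.1 s for temperature, with a tridiagonal solve per step; the linear
perfusion sink is folded into the implicit matrix.

Tissue parameters (specific heat, density, conductivity, perfusion, metabolic
heat) are tabulated for dermis, epidermis, fat, and tumor/muscle, with blood
at ρ = 1050 kg/m³, Cp = 3617 J/kg/°C, T_b = 37 °C. Perfusion rates are
volumetric (m³ blood per m³ tissue per s ≡ 1/s) and multiply ρ_b·Cp_b in the
sink term. Metabolic heat is stored volumetrically (W/m³) with the standard
magnitudes (muscle ≈ 991 W/m³): treating those magnitudes as per-kilogram
values and scaling by density would put the perfusion-balance baseline ~170 °C
above arterial temperature, which is nonphysical, so the volumetric reading is
used. The solver passes three oracles: exact equilibrium (T ≡ T_b with no
sources), the algebraic uniform-source steady state
T = T_b + (Q₀ + Q_met)/(ρ_b Cp_b ω_b) (sealed boundary), and grid convergence
of the centre temperature to < 0.5% under mesh halving.

Nanoparticle transport uses the same machinery with D = 6.2×10⁻¹¹ m²/s by
default (the one tabulated tissue diffusivity; configurable per run). The
initial bolus is a Gaussian at the tumor centre (σ = 0.5 mm — the width of a
central injection shortly after delivery; not independently constrained) whose
total count matches 40 µg/mL over the tumor volume via the solid-gold-sphere
mass. A uniform generation term (default off) is available. The diffusion
solver conserves particle number to < 0.1% with a sealed boundary and matches
the spherical heat-kernel solution (Gaussian stays Gaussian with variance
σ² + 2Dt) to < 1% RMS.

The heating term is Q(r) = c(r)·σ_abs·I with I = 20 W/cm² by default and
σ_abs taken at the spectrum peak. Beam attenuation through tissue is
neglected (no Beer–Lambert factor), every particle sees the incident
irradiance, and thermal feedback on the optics is ignored. Composed at the
stated study conditions these assumptions concentrate very large powers
(~10⁷ W/m³) at the tumor core and the predicted centre temperatures are far
above physiological plausibility (hundreds of °C); the model's meaningful
desk-scale outputs are the *shape* of the profile — the radius out to which
each damage threshold (42/47/50 °C) is exceeded and the decay toward baseline
in the healthy margin — which the tests assert, not the absolute core
temperature.

## Cell-death kinetics

Fast phase: dA/dt = −k_f A + k_b V, dD/dt = k_f V, V = 1 − A − D, with
k_f = k̄_f e^{T/T_k}(1 − A) (T in °C, as implied by T_k being quoted in °C).
Because A = 1 is a fixed point of the self-catalytic rate, simulations seed a
vulnerable fraction V₀ = 10⁻³ by default (configurable, recorded in trajectory
metadata). Slow phase: dD/dt = k_s(1 − D), k_s = k̄_s D(1−D)(D−D_τ)², with no
vulnerable pool. Shipped rate presets: melanoma (k̄_f = 0.25481 /min,
k_b = 0.66477 /min, T_k = 40.1513 °C, k̄_s = 0.59547 /h, D_τ = 4.5×10⁻⁴) and
prostate (k̄_f = 0.18946, k_b = 0.23063, T_k = 39.678, k̄_s = 3.16×10⁻⁴ /h,
D_τ = 0.208; the slow-phase pair is flagged `provenance="unverified"` — it was
published without supporting data). The melanoma D_τ is so small that the
slow-death threshold is effectively inert.

Public simulation calls integrate with LSODA at rtol 10⁻⁸ / atol 10⁻¹⁰ and
recover V algebraically from conservation; frozen reference values from an
independent Radau integration at rtol 10⁻¹² are asserted in tests. Parameter
estimation (`fit_death_params`) is bound-constrained least squares
(default bounds: rates in [10⁻⁴, 10], T_k in [30, 60] °C, D_τ in [0, 0.999])
with 20 multistarts drawn log-uniformly (rates) / uniformly (T_k, D_τ) from a
seeded generator. The fitting loop uses an internal fixed-step RK4 forward
model (the system is smooth and non-stiff; step count scales with the fastest
rate so extreme starts stay stable), which agrees with the adaptive integrator
to ~10⁻⁷ and keeps a 20-start fit under ~3 s. Identifiability caveat: a single
fixed-temperature survival curve constrains (k̄_f, T_k) only through
k̄_f·e^{T/T_k}, so recovered parameter vectors are not unique; the contract —
asserted in tests — is that the fitted survival curve matches truth (≤ 0.05
RMS in ≥ 90% of 50 seeded replicates at noise sd 0.02).

## Tumor course

Between sessions V(t) = V₀e^{a₀t} in closed form (no integrator). Growth-rate
presets: melanoma a₀ = 0.328 /day, melanoma under HSP90 inhibition 0.237 /day,
prostate 0.243 /day. The printed source unit for these rates is s⁻¹, which
would double a tumor in ~2 s; day⁻¹ is the only reading compatible with
multi-day growth data, and is what the package uses.

A session runs the fast phase (default melanoma: 48 °C, 30 min; prostate:
50 °C, 15 min), then the slow phase over a 48 h window truncated to the
inter-session gap when sessions are closer (prostate days 0→2). The coupling
to volume is proportional viable volume, V_post = V_pre(1 − D_final) — the
minimal assumption; V_post = V_pre·A_final is available for the reading where
vulnerable cells are also lost. Growth is suspended during the slow-death
window (death and growth treated as sequential phases), so a course with
period Δt days and window w shrinks net iff the per-session kill exceeds
1 − e^{−a₀(Δt − w/24)}. With the shipped melanoma parameters each session
kills ≈ 26%, below the ≈ 48% break-even, so the modeled course slows but does
not shrink the tumor; published shrinkage curves for this protocol are not
reproducible from the printed rate constants alone and presumably reflect
calibration against external viability data at face value. A guard floor
(viable fraction ≥ 10⁻⁶) keeps regrowth defined after a total-kill session.

## Synthetic data

`gen_viability` adds Gaussian noise (clipped to [0, 1]) to a model survival
curve at exactly the requested times; `gen_growth` multiplies exponential
volumes by log-normal noise, matching the additive-on-fractions /
multiplicative-on-volumes error structure typical of plate assays and caliper
measurements respectively. Seeds are mandatory; generating parameters are
recorded in `DataFrame.attrs`. What passing recovery tests shows: the
estimation machinery is unbiased and stable under the assumed noise model at
the assumed design (10 points / 30 min; 8 points / 14 days). What it does not
show: robustness to real-data pathologies — plate effects, non-Gaussian
outliers, model misspecification, inter-replicate drift.

## Problem sizes and determinism

Default problem sizes (241-node grids, 0.1–1 s heat steps, 1 nm spectral
grids, 20 multistarts, 50-replicate recovery suites) were chosen so the full
test suite and the acceptance script run on a single CPU in minutes while
keeping every numerical check at least an order of magnitude inside its
tolerance. All stochastic paths take explicit seeds; there is no global random
state, and pipeline reports are byte-identical across reruns.

## Known limitations

* No beam attenuation or EM field solution in tissue; the heat source is
  strictly local. Absolute temperatures under the default irradiance are far
  above physiological validity (see above).
* Quasi-static spheroids only; no retardation, no nanorod electrodynamics.
* Two-layer particles at most; no multi-shell structures.
* Single homogeneous healthy tissue around the tumor (no skin-layer stack),
  though any tabulated tissue can be placed there.
* Constant-temperature death kinetics by default; a time-varying temperature
  trace can be passed, but the shipped rate presets were calibrated at fixed
  temperatures.
* No thermal-dose (CEM43) model, no immune response, no inhibitor
  pharmacokinetics: HSP90 inhibition is a growth-rate change only.
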