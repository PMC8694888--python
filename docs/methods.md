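# Methods

`microemu` models a dispersion of oil-in-water microemulsion droplets
(radius R = 62 Å) decorated with N_p hydrophobically anchored PEO chains, in
saline water (0.2 mol l⁻¹ of 1:1 electrolyte). The pipeline has four layers —
effective pair potential, integral-equation theory, molecular dynamics, and a
small-angle neutron-scattering (SANS) model with a synthetic-spectrum
generator — each usable on its own.

## Effective pair potential

The droplet–droplet interaction is pairwise and additive,

    V(r) = U_core + U_vdW + U_Coulomb + V_steric,    [k_BT]

with r the centre-to-centre distance in Å and σ = 2R the contact diameter.

* **Core.** A continuous surrogate for the hard sphere, `(σ/r)^36`. A true
  discontinuous core is incompatible with a continuous integrator; the
  exponent 36 makes the droplet effectively impenetrable (1 k_BT at contact,
  44 k_BT at 0.9 σ) while keeping forces finite. The power law is used
  unmodified (no shifted-truncated construction): it decays below 1e-17 k_BT
  by 3σ on its own, and any truncation point would introduce a force
  discontinuity that the tabulation consistency check would flag.
* **van der Waals.** The Hamaker sphere–sphere energy
  `-(A_H/6)[2R²/(r²-4R²) + 2R²/r² + ln((r²-4R²)/r²)]` with A_H = 1.1 k_BT.
  The logarithmic divergence at contact is regularized by evaluating the
  expression at a surface separation of at least δ = 1 Å; the steep core
  makes smaller separations statistically unreachable at T* = 1. The clamp
  introduces one non-smooth point at r = σ + δ, which the force-consistency
  check excludes.
* **Screened Coulomb.** The DLVO renormalized Yukawa
  `Z_eff² l_B [e^{κR}/(1+κR)]² e^{-κr}/r` with Z_eff = 130, Bjerrum length
  l_B = e²/(4πε₀ε_r k_BT) = 7.006 Å (ε_r = 80, T = 298.15 K) and Debye
  length κ⁻¹ = (8π l_B n_salt)^(-1/2) = 6.867 Å at 0.2 M. Counter-ions from
  the droplet charge are neglected next to the added salt. The
  `[e^{κR}/(1+κR)]²` surface-exclusion prefactor matters: it raises the
  contact repulsion from ~1e-5 to 9.49 k_BT. Without it the bare dispersion
  has nothing to balance the −5 k_BT van der Waals well at the regularization
  gap and flocculates (the OZ solver finds no stable fluid solution), whereas
  the real bare system is charge-stabilized; the renormalized form is
  therefore the physically required reading.
* **Steric brush.** A contact-anchored Yukawa,
  `V_c (σ/r) e^{-(r-σ)/λ}`, with V_c = 0.65 N_p k_BT — matching the contact
  amplitudes 2.6/5.2/7.8 k_BT at N_p = 4/8/12 and extending linearly — and
  decay length λ = 25 Å, of the order of the radius of gyration of a 5.2 kDa
  PEO chain (R_g ≈ 0.02 M^0.58 nm ≈ 28 Å). λ is configurable in [15, 35] Å;
  it is the one genuinely uncertain model parameter, and the dilute-phase
  peak heights are the quantity most sensitive to it.

The total is shifted so V(R_c) = 0 at the cutoff R_c = 4R (the residual force
step there is < 1e-4 k_BT/Å). The stability barrier max_{r≥σ} V(r) grows
linearly with N_p: 5.50, 8.09, 10.68, 13.27 k_BT for N_p = 0, 4, 8, 12.

Tabulation uses a uniform 4096-point grid on [0.9σ, R_c] with analytic
forces, cross-checked against central differences (0.1 % of max|F|, excluding
the vdW clamp point).

**Reduced units** for everything downstream: length R, energy k_BT, mass
m = 1, hence time τ = R√(m/k_BT), diffusion R²/τ, pressure k_BT/R³,
compressibility R³/k_BT.

## Ornstein–Zernike / HNC

The OZ relation `h = c + ρ c*h` is closed with the hypernetted-chain
approximation `c = exp(-βV + γ) - γ - 1` (γ = h − c) and solved by Picard
iteration on γ with fixed mixing 0.1, tolerance 1e-8 on max|Δγ|, at most
20 000 sweeps. Radial Fourier transforms use the type-I discrete sine
transform on n_r = 8192 points with dr = 0.01 σ (the grid spans 82 diameters;
halving dr and doubling n_r moves the main-peak height by < 0.5 %). The
closure input is the bare pair potential — no bridge correction. Number
density follows from the hard-core volume fraction, ρ = 3Φ/(4πR³).

Thermodynamic routes: energy `(ρ/2)∫ βV g 4πr²dr` (ideal 3/2 k_BT reported
separately), virial pressure `ρ - (ρ²/6)∫ r V' g 4πr²dr`, and compressibility
`χ_T = [1 + ρ∫h 4πr²dr]/ρ`. S(q) = 1 + ρĥ(q); the S(q→0) limit is a
quadratic extrapolation through the three smallest grid wavenumbers and
satisfies the compressibility sum rule S(0) = ρ k_BT χ_T to better than 1 %
at both studied densities.

At the study conditions (λ = 25 Å, N_p = 4) the solver gives main-peak
heights g_max ≈ 2.24 at Φ = 26.5 % and ≈ 1.15 at Φ = 6.98 %.

## Molecular dynamics

Velocity-Verlet NVT in a cubic periodic box, dt = 0.001 τ, T* = 1. Forces
come from linear interpolation of the tabulated potential through a
linked-cell list (27-cell sweep, exactly matched by the O(N²) reference
implementation to 1e-12). Equilibration (5000 steps from a simple-cubic
lattice with Maxwell–Boltzmann velocities, net momentum removed) uses
per-step velocity rescaling; production uses a single Nosé–Hoover thermostat
with time constant 100 dt, which is deterministic and momentum-conserving so
transport coefficients remain meaningful; pure NVE production is available.

Desk-scale study conditions: N = 1000 droplets per state point, production
36 τ (dilute, Φ = 6.98 %) and 24 τ (concentrated, Φ = 26.5 %), frames every
10 steps, for the 2 × 4 grid of volume fractions and grafting numbers.
Doubling N or the production length moves the structure peaks by under 2 %.

Energy conservation with the thermostat off is integrator-limited: at
dt = 0.001 the total energy wanders by ~2e-3 k_BT/particle over 10⁴ steps
(the screened-Coulomb contact region is stiff, κ⁻¹ ≈ 0.11 R); halving dt
reduces this below 1e-3, the dt² scaling expected of velocity Verlet.

## Trajectory analysis

* **g(r).** Minimum-image pair histogram to L/2, ideal-gas shell
  normalization, frames decimated tenfold for decorrelation.
* **S(q).** Two estimators. The Fourier route
  `S(q) = 1 + ρ∫(g-1) sinc(qr) 4πr² dr` with a raised-cosine taper over the
  outer quarter of the histogram range (widened automatically, with a
  warning, if truncation ripple drives S negative); reliable at and above
  the main peak.
  The direct route `⟨|Σ e^{iq·r}|²⟩/N` on box-commensurate wavevectors; free
  of the fixed-N constraint bias that depresses the Fourier route at the
  smallest q (in a closed box the pair histogram integrates to N−1, not
  N S(0)), so S(0) is estimated by a quadratic fit to the direct estimator
  over the shells below q ≈ 1/R. Peak height/position use parabolic
  interpolation through the three bins around the maximum; d = 2π/q_max is
  also reported in Å, alongside the g(r) first-peak position (the two differ
  by construction).
* **MSD.** Multiple-time-origin average on log-spaced lags from unwrapped
  coordinates. The ballistic amplitude (slope-2 log–log fit over t ≤ 0.1)
  recovers 3 T*/m. Normal diffusion is fit as MSD = 6Dt over the last decade
  of lags; anomalous fits are log-linear.
* **Crossover time.** t₁ is the intersection of the slope-2 ballistic
  asymptote with the late-time asymptote (slope 1, or free α for the dense
  intermediate regime): t₁ = (6D/A)^{1/(2-α)}. With A = 3T* and α = 1 this
  is exactly t₁ = 2D — the crossover and the diffusion coefficient are not
  independent numbers under this definition.
* **Intermediate regime.** A half-decade window scan seeks the most linear
  log–log stretch with exponent α < 1 (caging). At these conditions the MSD
  exponent relaxes from 2 to 1 monotonically — the minimum local slope is
  ≈ 1.0 even at N_p = 12, under both Nosé–Hoover and NVE production — so no
  true sub-diffusive plateau exists at Φ = 26.5 % with this potential. When
  the scan finds none, the anomalous fit is reported on the knee window
  (minimum local slope) instead, with its α attached; consumers should treat
  D_α there as a crossover-region amplitude, not a genuine sub-diffusion
  coefficient.
* **Trends.** D versus N_p by ordinary least squares with standard errors;
  exact on exactly linear input.

## SANS model and synthetic spectra

Absolute-scale intensity `I(q) = Φ v (Δρ)² P(q) S(q)` in cm⁻¹, with
v = (4π/3)R̄³ (single Å→cm conversion point) and contrast
Δρ = 6.83e10 cm⁻². P(q) is the sphere form factor averaged over a Gaussian
radius distribution (mean R̄ = 62 Å, width ΔR = 6.2 Å, truncated at ±4ΔR)
with v(R)² weighting — the intensity-weighted convention — renormalized so
P(0) = 1 exactly; 64-node Gauss–Legendre quadrature is converged to 1e-8
(128 nodes change nothing at that level).

The synthetic generator evaluates the model on a 120-point log-spaced grid
over 0.004–0.16 Å⁻¹ and multiplies independent unit-mean lognormal noise at
10 % relative scale — the absolute-calibration accuracy typical of the
instrument class. What it deliberately does **not** emulate: instrument
resolution smearing (wavelength spread, collimation), incoherent/solvent
background, and detector-level artefacts. Passing round-trip tests therefore
show estimator correctness at the stated noise, not robustness to resolution
effects.

The (R̄, ΔR, scale) fit is weighted least squares in the Porod plane
q⁴I(q)/Φ, restricted to q ≥ 0.04 Å⁻¹ where S(q) ≈ 1 at both volume
fractions (the structure peak lies near 0.04 Å⁻¹ and below); the spectrum
must cover the first form-factor oscillation (q_max ≥ 6/R̄). Dividing a
spectrum by the fitted P̄ recovers S(q); points where P̄ < 5e-3 (form-factor
minima) are masked, not extrapolated. Noise-free round trips recover
(62, 6.2) to 0.1 %; at 10 % noise R̄ comes back within 2 %.

## Known limitations

* The HNC closure underestimates the structure-factor main peak by ~8 %
  relative to MD at Φ = 26.5 % (g(r) peaks agree within ~3 %); this is
  closure error, not a solver defect.
* Desk-scale S(0) carries the statistical noise of the low-q direct
  estimator (a few percent absolute at these run lengths).
* No hydrodynamic interactions: diffusion coefficients are those of the
  conservative reduced-unit dynamics, not Stokes–Einstein values.
* No sub-diffusive caging exists at Φ = 26.5 % with this potential (see
  above); anomalous-regime outputs at that density describe the
  ballistic-to-diffusive knee.
* λ_steric is order-of-magnitude constrained only; dilute-phase peak heights
  shift by several percent across its admissible range [15, 35] Å.
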