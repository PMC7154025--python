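# Methods

`pulsetwin` is a desk-scale, lumped-parameter ("0D") twin of a ViVitro-style
pulse-duplicator test of bioprosthetic aortic heart valves (BHVs).  It
reproduces, at the level of bulk hemodynamics, the model chain used to
validate three-dimensional fluid–structure interaction (FSI) simulations of
two surgical valves — a glutaraldehyde-fixed porcine aortic valve and a
bovine pericardial valve — against pulse-duplicator measurements.  The 3D
FSI solve itself (immersed-boundary flow, finite-element leaflets, turbulent
jet dynamics) is deliberately out of scope; a 0D valve surrogate stands in
for it, and a synthetic-experiment generator stands in for the unavailable
laboratory recordings.

## Leaflet constitutive model

Leaflets are incompressible, anisotropic, hyperelastic.  The strain energy
splits into isochoric and volumetric parts,

    Psi(F) = W(F̄) + U(J),    F̄ = J^(-1/3) F,  J = det F,

with a Holzapfel–Gasser–Ogden-type isochoric energy

    W_iso   = C10 [ exp(C01 (Ī₁ − 3)) − 1 ]
    W_aniso = k1/(2 k2) { exp[ k2 (κ Ī₁ + (1 − 3κ) Ī₄* − 1)² ] − 1 }

where Ī₁ = tr C̄, Ī₄* = max(e₀ᵀ C̄ e₀, 1) (fibers carry load in extension
only), e₀ is the mean fiber direction, and κ ∈ [0, 1/3] is the fiber angle
dispersion (0 = perfectly aligned, 1/3 = isotropic).  The volumetric
stabilization is U(J) = β (J ln J − J + 1).  Parameter sets (stress-like
constants converted from MPa to kPa on load, conversions round-trip tested):

| parameter | porcine | pericardial | units |
|---|---|---|---|
| C10 | 0.302 | 0.119 | kPa |
| C01 | 3.25 | 22.59 | – |
| k1 | 0.197 | 2.38 | MPa |
| k2 | 0.001 | 149.8 | – |
| κ | 0.0 | 0.292 | – |
| fiber angle | 0° | 45° | in-plane |

β = 14.1 MPa is retained for API completeness; the membrane computations
treat the tissue as exactly incompressible (J = 1 by construction), so the
volumetric term never activates there.

Numerical care: both exponentials are evaluated through `expm1`, so the
porcine fiber term (k2 = 0.001, a nearly quadratic regime) does not suffer
cancellation in the k1/(2 k2) prefactor; the analytic k2 → 0 limit
(k1/2) E² is used at k2 = 0 exactly.  The fiber-exponent argument is guarded
at 250 and raises a named overflow error beyond it.  The first
Piola–Kirchhoff stress is the analytic gradient ∂Ψ/∂F; the test suite
checks it against central finite differences to < 1e-6 relative on random
volume-preserving deformations for both parameter sets.  The clamp
Ī₄* = max(Ī₄, 1) makes the energy C¹ but not C² at Ī₄ = 1; test points
avoid differencing across that kink.

The wall of the (glass, effectively rigid) aortic test section is retained
as a penalty model: a stiff neo-Hookean energy with c_wall = 33.1 kPa plus a
tether force density κ_wall (X − χ), κ_wall = 852 MPa cm⁻².

### Plane-stress biaxial response and fitting

Biaxial membrane states use F = diag(λ₁, λ₂, (λ₁λ₂)⁻¹) with the hydrostatic
pressure eliminated by the traction-free thickness direction (σ₃₃ = 0).  The
original leaflet datasets (Billiar–Sacks porcine, Kim et al. pericardial)
are not redistributable, so fitting is exercised on synthetic protocols
generated from the printed parameter sets: equibiaxial λ ∈ [1, 1.15] plus
two constrained strip-biaxial protocols (λ₂ = 1, then λ₁ = 1), 30 points
each — a design chosen to make κ and k2 identifiable.  The objective is
unweighted least squares on the stacked in-plane Cauchy stresses (the
original study does not state its objective; stress residuals are the
simplest defensible choice), multi-started within bounds.  Noise-free
recovery is exact to machine precision; under 2% multiplicative noise the
porcine k2 = 0.001 is practically unidentifiable (its effect on stress is
~1e-4 relative) while all other constants stay within a few percent — the
recovery tests therefore track k1, not k2.  Single-protocol data with κ free
triggers a non-identifiability warning.

## Circuit models

The rig is a lumped hydraulic network with ground (reservoir) at 0 mmHg.
Printed compliances are interpreted as mL/mmHg: the tabulated magnitudes
(C = 0.915, 1.27) are only physically sensible in that unit even though the
source tables print mmHg mL⁻¹.

Downstream load, both rigs — three-element Windkessel:
p_in = q R_c + p_store, C dp_store/dt = q − p_store/R_p, with
(R_c, R_p, C) = (0.0218, 1.31, 0.915) porcine and (0.0282, 1.22, 1.27)
pericardial (resistances mmHg s/mL).  The porcine diastolic decay constant
R_p C = 1.19865 s is verified against simulation.

Upstream, porcine: pressure source → R₁ = 0.15 → VIA node
(C_VIA = 0.1 mL/mmHg) → R₂ = 0.15 → ventricular node → valve.  The
ventricular node needs a state; a small regularizing compliance
C_LV = 0.02 mL/mmHg is introduced (a modeling device of this package —
stroke-volume sensitivity to it is well under 1%).

Upstream, pericardial: flow source into node V1 (C_VIA1 = 0.0275), V1 →
R_VIA = 0.15 → ventricular node V2 (C_VIA2 = 0.0347), atrial source
(constant 10 mmHg) → mitral diode (R_MV = 0.0280) → V2, and a return path
R_out = 0.0898 from V1 to ground.  The schematic does not pin down the
placement of R_out; V1 → ground is this package's documented default and the
topology is config-declared so alternatives are testable.  The diode uses a
C¹ smoothing of width 0.01 mmHg: q = (Δp + √(Δp² + ε²)) / 2R.

Working fluid: saline (ρ = 1.0 g/cm³, μ = 1.0 cP); a blood-analogue preset
(μ = 3.5 cP) is available.

### Integration

State vector: node pressures, valve opening fraction θ, valve flow q (the
orifice law carries an inertance, making q dynamic).  Cycles run at 70 bpm
(period 60/70 s).  The closed valve leaks through a 0.001·EOA orifice, whose
quadratic resistance gives the flow state a microsecond-scale local time
constant during diastole — the system is stiff there, so the default
integrator is LSODA (max step 1e-4 s, rtol 1e-7), which switches to a stiff
method automatically; any `solve_ivp` method can be selected.  The solver
runs cycle-by-cycle until the trajectory sampled at 1 kHz repeats to a
relative L2 tolerance of 1e-3 (typically 3–10 cycles from the pre-charged
initial state: aortic store 80 mmHg, other nodes 10 mmHg).  Halving the
step changes the converged cycle by < 0.1%.

## Valve surrogate

The reference study has no 0D valve law — its valve resistance emerges from
the 3D FSI solve — so the surrogate is an explicit modeling substitution:

* opening fraction θ ∈ [0, 1] with a Mynard-type rate law,
  dθ/dt = k_open (1 − θ) Δp for Δp ≥ 0 and k_close θ Δp otherwise;
* effective orifice area A_eff = a_leak + (a_max − a_leak) θ, a_leak
  defaulting to 0.001 a_max (near-complete closure, mirroring the reference
  valves, which seal fully);
* Bernoulli orifice law Δp = (ρ/2) q|q|/A_eff² (converted dyn/cm² → mmHg)
  plus an inertance L dq/dt with L = 4e-4 mmHg s²/mL (ρ·l_eff/A for a
  ~1 cm effective orifice length);
* EOA calibration by Gorlin-style inversion,
  EOA = Q_peak √(ρ / 2 ΔP_peak), giving 1.84 cm² (porcine, from
  452.5 mL/s and 22.8 mmHg) and 1.86 cm² (pericardial, 425.1 mL/s and
  19.7 mmHg);
* a quasi-static diastolic membrane state: the closed leaflet is idealized
  as a pressurized spherical cap (radius 1.25 cm, thickness 0.04 cm) whose
  equibiaxial tension T(λ) = thickness · mean in-plane Cauchy stress
  balances Laplace's law T = Δp R/2; the stretch is found by bracketing
  Brent iteration and cross-checked against a fine-grid scan.

Rate constants default to k_open = k_close = 3 /(mmHg s): at the 10–25 mmHg
transvalvular differences of this rig, opening and closing then complete in
tens of milliseconds, consistent with the frame-to-frame timing of the
reference kinematics.  PDVA is reported as pdva_scale · θ with
pdva_scale = EOA/0.7 (a discharge-coefficient convention of this surrogate,
not a claim of the reference study).  Leaflet flutter is intentionally not
part of the surrogate — the reference model itself shows flutter
discrepancies — and appears only in the synthetic-experiment generator.

## Calibration of the twin

A smooth periodic ejection pulse (sin² bump, initial width 0.24 s) drives
each rig: a pressure source for the porcine configuration, a flow source for
the pericardial one.  A deterministic fixed-point loop adjusts

* the driver amplitude by the peak-flow ratio (Q_peak ≈ linear in amplitude),
* the driver width by the residual stroke-volume ratio (SV ≈ amplitude × width),
* the orifice area by a bounded ±10% trim with Δp ∝ 1/A² (the closed-form
  EOA inversion ignores the inertance and the opening transient, which
  otherwise leave a ~1% systematic excess in the peak pressure difference),

until the converged cycle matches the preset targets — forward stroke
volume, peak flow, peak forward ΔP — to 0.1%.  Targets are the published
experimental values: SV 69.4 / 71.6 mL, ΔP_max 22.8 / 19.7 mmHg, and peak
flows 452.5 / 425.1 mL/s implied by the printed peak Reynolds numbers
(20,576 and 19,330) through Re = ρ Q D/(μ A) with D = 2.8 cm.  Successive
iterations warm-start from the previous periodic state; full calibration
takes ~10 iterations (a few seconds).

## Synthetic-experiment generator

The generator replays the calibrated twin's converged cycle with the
statistical structure of the measurement chain:

* per-cycle multiplicative amplitude jitter — one factor per cycle on the
  flow channel with CV = SV_sd/SV_mean, one on both pressure channels with
  CV = ΔP_sd/ΔP_mean (so the transvalvular difference inherits it).  The
  published ± values are treated as 10-cycle standard deviations (they could
  alternatively be 95% half-widths; SDs are the conservative reading);
* additive white sensor noise (0.3 mmHg on pressures, 2 mL/s on flow);
* zero-phase 4th-order Butterworth low-pass at 100 Hz on the channels the
  acquisition protocol filters (porcine: pressures and flow; pericardial:
  flow only — its pressure channels are recorded unfiltered); PDVA is never
  filtered;
* synthetic systolic leaflet flutter on PDVA: a damped 40 Hz oscillation
  (amplitude 5% of peak PDVA, 0.1 s decay) while the valve is open.  The
  flutter frequency and amplitude are free parameters — the reference study
  reports flutter discrepancies without printing frequencies.

All randomness flows through one seeded `numpy` generator recorded in the
dataset metadata; a fixed seed reproduces the CSV byte-for-byte.  With noise
and filtering disabled the cycles equal the twin's converged cycle exactly.

What the generator does **not** emulate: beat-to-beat waveform-shape
variability (jitter is amplitude-only), drift, transducer phase lags,
quantization, or genuine flow turbulence.  Passing tests therefore show the
pipeline's internal consistency at the published summary statistics, not
agreement with any real laboratory recording.

## Validation metrics

* Relative discrepancy ‖sim − exp‖_q / ‖exp‖_q, q = 2 (trapezoidal
  quadrature on the experimental 1 kHz grid) and q = ∞ (max absolute),
  over one period; the simulation is linearly resampled onto the
  experimental grid, after aligning cycles at the beginning of valve opening
  (the convention used for the reference PDVA comparisons).  Norms are
  computed over one converged cycle (whether the reference table used one or
  several cycles is not stated; for periodic signals the relative norms are
  insensitive to that choice).
* Forward stroke volume: trapezoidal integral of the positive part of
  aortic flow per cycle (the source does not define its stroke volume; the
  forward-volume convention is standard for pulse duplicators, and the net
  volume is reported alongside for transparency).
* Maximum forward-flow pressure difference: max of P_LV − P_Ao restricted
  to samples with positive aortic flow.
* Peak Reynolds number: Re = ρ Q_peak D/(μ A), A = πD²/4, D = 2.8 cm.
* Ensemble statistics: pointwise mean and central 95% band
  (2.5/97.5 percentiles) over phase-aligned cycles.

## Problem sizes and determinism

Default problem sizes: 1 kHz output sampling (857 samples/cycle at 70 bpm),
periodic convergence at 1e-3 relative L2, 50-cycle synthetic datasets for
ensemble statistics, 30-point × 3-protocol biaxial tables, 20-replicate
noisy-fit studies.  These are the package's standard configurations; every
entry point accepts larger values.  All stochastic stages take explicit
seeds; the twin calibration is deterministic.

## Known limitations

* The valve surrogate has a single opening degree of freedom: no
  per-leaflet dynamics, no sequential closure, no commissural stress maps,
  no flutter.  Pressures and flows during the opening/closing transients are
  therefore smoother than a 3D model's.
* The pericardial twin matches the *experimental* targets by construction;
  the reference pericardial simulation's ΔP_max (16.4 mmHg) differs from
  the experiment (19.7 mmHg) by 16.5%, a mismatch a 0D surrogate cannot and
  should not reproduce.
* Viscoelasticity of the leaflets is not modeled (also a stated limitation
  of the reference study).
* The membrane diastolic state uses an equibiaxial spherical-cap
  idealization; it exercises the constitutive law but does not predict the
  3D stress distribution.
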