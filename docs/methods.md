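# Methods

This note describes the models implemented in `pppa`, the choices made
where the design was genuinely open, and what the synthetic experiments do
and do not establish.

## Contrast mechanism and the two-level model

Pump-probe photoacoustic (PA) contrast exploits the nanosecond excited-state
lifetime of fluorophores.  A pump pulse tuned to the absorption band
transiently depopulates the ground state; a probe pulse tuned to the
emission band drives stimulated emission (SE), returning molecules to the
ground state and enabling additional excitation cycles within the same
pulse.  The thermalized energy — and with it the initial acoustic pressure
`p0 = Γ·H` — therefore depends on the pump-probe delay Δt.  Subtracting the
signal acquired at Δt ≫ τ from the one at Δt = 0 yields a difference signal
that is specific to fluorophores: a linear (fast-relaxing) absorber has no
population memory, so its difference vanishes identically.

`pppa.photophysics` implements the minimal scheme that produces all of
these effects: an effective two-level system (ground `N0`, relaxed excited
`N1`, instantaneous vibrational relaxation) coupled to quasi-static 1D
photon transport,

    dN1/dt = [σ_a(λ_pu) F_pu + σ_a(λ_pr) F_pr] N0
             − N1/τ
             − [σ_e(λ_pu) F_pu + σ_e(λ_pr) F_pr] N1,

with local photon fluxes `F_x` attenuated (or amplified, via SE) layer by
layer with the *current* populations, `μ(z) = σ_a N0(z) − σ_e N1(z)`.
Residual probe absorption (σ_a at the probe wavelength) and SE driven by
the pump (σ_e at the pump wavelength) are both included; two-photon
absorption, excited-state absorption and triplet states are not.

**Energy bookkeeping.**  With `E_gap = hc/λ_em,peak`: absorption of a
photon at λ thermalizes `hc/λ − E_gap` promptly; non-radiative decay
deposits `E_gap`; spontaneous radiative decay removes `E_gap` with
probability φ_q; SE at λ returns `hc/λ` to the beam and thermalizes the
signed remainder `E_gap − hc/λ`.  The remainder is deliberately *not*
floored at zero: a small negative deposit (stimulated emission out of a
level above the effective gap) is the price of an exactly closed budget,
and with the integrator below the identity
`absorbed = heat + fluoresced + se_returned` holds to machine precision.

**Numerics.**  Time steps default to FWHM/100 (0.03 ns for 3 ns pulses).
Within each step the fluxes are frozen and the linear population ODE is
solved exactly (exponential integrator), together with its exact time
integrals; event counts (absorptions, SE, decays) derived from those
integrals satisfy the population balance identically, which is what makes
the energy budget close exactly rather than to O(dt).  The stiff τ → 0
limit is therefore handled without resolving τ (the quasi-steady state is
exact per step), and only `dt ≤ FWHM/50` is enforced.  Excited population
remaining after the pulses is flushed analytically (all decay heat lands
well within the acoustic stress-confinement time).  Temporal pulses are
Gaussians truncated at ±3σ; linear absorbers take the closed-form
Beer-Lambert solution.  Halving dt and doubling the 500-layer depth grid
changes the integrated difference energy by about 0.2 %.

## Fluorophore presets

No machine-readable spectra exist for the three proteins, so the presets
ship *synthetic surrogate* spectra: absorption = Gaussian main band
(FWHM 60 nm) plus a 0.3-amplitude vibronic shoulder 30 nm to the blue,
re-centered so the composite peaks exactly at the nominal wavelength;
emission = unit-peak Gaussian (FWHM 70 nm).  Peak positions are chosen so
the Katushka band lies exactly 20 nm blue of mNeptune/mCardinal
(588/608/608 nm absorption; 635/655/659 nm emission).  Lifetimes (2.0,
1.4, 1.4 ns) and concentrations (67, 65, 50 µM) are the study conditions;
peak extinctions (65 000, 67 000, 87 000 M⁻¹cm⁻¹) and quantum yields
(0.34, 0.20, 0.19) are literature-typical surrogates.  The SE cross
section is modeled as the emission shape scaled to the peak absorption
cross section (`se_peak_ratio`, default 1.0) — its absolute magnitude is
not constrained by any tabulated value and is configurable.  An asymmetric
(lognormal) emission surrogate was evaluated and did not change any
conclusion, so the simpler Gaussian is kept.

The non-fluorescent CrCl₃/CoCl₂ reference absorber defaults to a smooth
µ_a ramp from 1 cm⁻¹ (500 nm) to 4 cm⁻¹ (680 nm).

## Detection and the processing chain

The cuvette detector is modeled as an AC-coupled, band-limited
differentiator: plane-wave retardation maps depth z to arrival
`t = t0 + (L−z)/c_s` (the back window arrives first), the waveform is the
time derivative of the retarded p0 profile, and the band response is a
first-order high-pass at 0.02 MHz cascaded with a fourth-order Butterworth
low-pass at 37 MHz, applied zero-phase.  Two points are deliberate:

* modeling the detector as differentiating makes the downstream
  time-integration step an exact first-order inverse, by construction;
* the AC corner is kept at 0.02 MHz (period 50 µs ≫ the 3.6 µs cuvette
  transit) and first order, because a steeper or higher corner visibly
  distorts the recovered p0 profile over a window this long.  The corner
  is a surrogate — the real transducer's transfer function is unknown —
  calibrated only so that the package's own processing chain is
  self-consistent (integration round trip r > 0.99 against the
  band-limited p0).

Processing follows the measurement convention: normalize by
absorption-weighted pulse fluences,
`k = (µ_a,pu + µ_a,pr) / (µ_a,pu Φ_pu + µ_a,pr Φ_pr)`; Butterworth
low-pass at 15 MHz (order 4, zero phase; the design frequency is adjusted
so the forward-backward response is −3 dB at the stated cutoff); repeat
averaging with standard error; cumulative trapezoidal time integration
anchored at the pre-arrival baseline (mean of the first 10 % of samples).

**TIDSA metric.**  The scalar "time-integrated difference signal
amplitude" is defined here as the absolute *time integral of the
integrated difference trace over the cuvette arrival window* — i.e. the
total difference in thermalized energy across the cuvette.  At the study
fluences (12 mJ/cm², σ_a Φ/hν ≈ 9 at the absorption peak) the model is
deeply saturated and the per-depth peak of the difference profile develops
a dip at the absorption maximum; the net-energy metric is insensitive to
this redistribution and tracks µ_a(λ_pu) at all fluences, which is the
behavior the method is built on.  The peak metric remains available
(`tidsa_metric(..., mode="peak")`) and is used for single-pulse TISA
spectra, where the peak of the integrated trace (the surface p0) is the
conventional amplitude and reproduces the saturation blue-shift of
single-pulse spectra.

## Scans and lifetime recovery

Pump scans run 500–660 nm (5 nm), probe scans 570–680 nm (5 nm), delay
scans 0–10 ns (1 ns), with λ_pr = 650 nm / λ_pu = 580 nm fixed and
Φ0 = 12 mJ/cm² per pulse as defaults.  Delay scans difference each delay
against the longest delay in the grid and normalize to the Δt = 0 value.

Lifetimes are recovered by least squares against the closed form of an
exponential decay convolved with a Gaussian of width
σ_eff = √2·FWHM/2.355 (the cross-correlation width of two equal pulses),
with free amplitude and offset.  On its own closed-form data the fit is
exact to <10⁻³.  On simulated scans the recovered τ carries a systematic,
regime-dependent bias because the true decay is not exactly a convolved
exponential: pump-driven recycling during the pulse overlap and probe
saturation add components with faster delay dependence.  At the default
conditions the preset lifetimes are recovered within 10 % (Katushka
2.0 → 1.91 ns; mNeptune 1.4 → 1.27 ns), while across a wider τ grid
(1–3 ns) the bias reaches ~20 % at the edges.  This is a property of the
estimator-model mismatch, not of the optimizer, and is left visible
rather than recalibrated away.

## Where the model departs from the reported phenomenology

Two observed behaviors are *not* reproduced by this minimal scheme at the
stated study conditions, and the corresponding acceptance-style tests are
left failing rather than weakened:

* **Fluence invariance of difference spectra.**  The unit-peak pump-probe
  difference spectra retain a saturation-driven fluence dependence
  (shape-RMS ≈ 0.09–0.17 between Φ0, Φ0/2, Φ0/4 instead of < 0.05), and
  by the same token the near-source difference is negative (SE removes
  more energy per event, `E_gap − hc/λ_pr + φ_q`-weighted decay heat, than
  the extra absorption cycles deposit at φ_q ≈ 0.2–0.34).  The single-pulse
  distortion phenomenology (blue shift, distortion strictly increasing
  with fluence) *is* reproduced.
* **Protein-specific early-delay behavior.**  In the model the small rise
  of the difference signal between 0 and 1 ns is driven by the
  pulse-overlap convolution lag and therefore *grows* with τ (Katushka
  rises most), whereas the reported behavior has the proteins with
  residual probe absorption rising and Katushka decaying monotonically.
  Residual probe absorption in this scheme slightly *suppresses* the early
  rise.

Both points indicate that the real contrast involves physics beyond the
effective two-level scheme with these surrogate magnitudes (or different
effective cross sections); they are documented here and in the test suite
rather than hidden by parameter adjustment.

## Tomography

The phantom is three 1.47 mm ID tubes (Katushka, mNeptune, absorber) 4 mm
from the axis of a 512-element ring array (radius 40 mm, 5.5 MHz center,
55 % bandwidth, modeled as an order-2 Butterworth bandpass 4.0–7.0 MHz,
2048 samples at 40 MHz, ideal point elements).  Per-pixel p0 uses the
optically thin 0-D limit of the rate equations at the incident fluence
(`illumination="uniform"`, the documented small-tube approximation); a
depth-resolved alternative (`"slab8"`: 1D slab solve over the tube
diameter mapped to 8-direction chord depths) is available and matters when
µ_a·d is not small.

The acoustic forward model is the 2D spherical-mean (circular Radon)
projection: per element, the circular mean of p0 over radius c_s·t,
differentiated in time and band-limited.  Two discretization choices are
load-bearing: pixels are splatted linearly onto radial bins, and the mean
is normalized by the full circumference 2πr (zero-padding outside the
FOV) — normalizing by in-FOV pixel counts couples the square FOV into the
element response and makes the reconstruction gain position-dependent.
The default pixel pitch is 0.05 mm; at 0.1 mm (the half-wavelength limit
of the array band) rim discretization makes reconstructed amplitudes
direction-dependent at the tens-of-percent level, at 0.05 mm the spread is
~6 %.  Reconstruction is delay-and-sum backprojection with the
universal-backprojection weighting `s − t·ds/dt` by default (it suppresses
arc artifacts by an order of magnitude); plain delay-and-sum is available.

A band of 4–7 MHz cannot represent the flat interior of a 1.47 mm tube:
reconstructions are rim-encoded, and absolute interior amplitudes are not
observable.  Difference images cancel the absorber tube exactly in the
forward model; residual absorber-ROI intensity in reconstructions (<5 % of
the brightest fluorophore tube) is backprojection arc leakage from the
fluorophore tubes.

**Unmixing and NEC.**  Per-pixel nonnegative least squares over the pump
grid (default window 600–640 nm), after orienting the difference images so
the dominant signal is positive (the model's difference is negative
overall; NNLS needs a sign-coherent cube).  Reference spectra are exposed
three ways: literature absorption spectra, cuvette pump-scan TIDSA
spectra, and tube-calibrated spectra (`tube_reference_spectra`, the
in-silico analogue of calibrating on single-species tube phantoms).  Under
saturation these differ in shape; tube-calibrated references keep the
inversion consistent with the imaging forward model and are the default
for quantitative use.  With cuvette-scan references the saturated tube
spectra are misassigned at the tens-of-percent level — a real limitation
of transferring references between geometries in the saturated regime.
NEC is `σ_c·c/c0,max` with σ_c the background standard deviation of the
recovered map outside all ROIs; the full noiseless pipeline yields
sub-µM NEC (≈0.8–0.9 µM for ~70 µM tubes), dominated by reconstruction
artifacts rather than channel noise.

## Synthetic data vs. real data

The generator reproduces the *mechanistic* structure of the experiment:
band shapes, lifetimes, concentrations, pulse parameters, fluence ranges,
detector bands and geometry.  It does not reproduce: measured spectral
fine structure, the OPO pulse-energy wavelength dependence (available as
an optional multiplicative profile, off by default), transducer
diffraction and focusing, acoustic attenuation, cuvette reverberations, or
in-vivo spectral coloring.  Passing tests therefore establish internal
consistency of the method chain — contrast specificity, spectral
encoding, lifetime recovery, multiplexed unmixing — under controlled
conditions, not quantitative agreement with any particular measured
dataset.

## Problem sizes

Default problem sizes were chosen so every pipeline stage runs in seconds:
500 depth layers × ~600 time steps per cuvette simulation; 33-point pump
scans (two simulations per point); 21-point delay scans; 320² phantom
pixels × 512 elements × 2048 samples per tomographic acquisition.
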