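# pppa — pump-probe photoacoustic spectroscopy and imaging, in silico

`pppa` simulates and analyzes pump-probe photoacoustic (PA) experiments on
fluorescent proteins: the kind of measurement in which two co-aligned
nanosecond pulses — a *pump* tuned to the absorption band and a *probe*
tuned to the emission band — excite a fluorophore solution either
simultaneously or with a delay Δt, and the **difference** of the two PA
signals isolates the fluorophore from any non-fluorescent absorber
background.  The package is written for researchers in photoacoustic /
optoacoustic molecular imaging who want a fully synthetic, end-to-end
testbed for this contrast mechanism: every stage from excited-state
kinetics to tomographic unmixing is computable with no experimental data.

## What it models

The contrast arises because fluorophores stay excited for nanoseconds
(lifetime τ), comparable to the pulse duration.  A two-level system
(ground N0, excited N1) is driven by the local photon fluxes of both
beams,

    dN1/dt = [σ_a(λ_pu)·F_pu + σ_a(λ_pr)·F_pr]·N0 − N1/τ
             − [σ_e(λ_pu)·F_pu + σ_e(λ_pr)·F_pr]·N1,

coupled to 1D light transport with dynamic absorption
μ(z) = σ_a·N0(z) − σ_e·N1(z).  Stimulated emission by the probe recycles
molecules to the ground state, changing the thermalized energy H(z) and
the initial pressure p0 = Γ·H; a fast-relaxing absorber has no such memory
and its difference signal vanishes.  On top of this core the package
provides:

* **fluorophores** — spectral/photophysical models with presets for
  Katushka (τ = 2.0 ns, 67 µM), mNeptune (1.4 ns, 65 µM) and mCardinal
  (1.4 ns, 50 µM), plus a CrCl₃/CoCl₂ reference absorber (µ_a 1–4 cm⁻¹).
  Preset spectra are synthetic Gaussian surrogates (see `docs/methods.md`).
* **photophysics** — the dual-pulse solver (exact exponential integrator,
  machine-precision energy budget).
* **acquisition** — band-limited AC-coupled detector model for the 5.3 mm
  cuvette; reproducible additive noise.
* **signal_processing** — fluence normalization weighted by µ_a, 15 MHz
  zero-phase Butterworth low-pass, repeat averaging, time integration, and
  the TIDSA statistic (time-integrated difference signal amplitude).
* **scan_analysis** — pump-wavelength, probe-wavelength and delay scans;
  fluence series (single-pulse vs pump-probe); lifetime recovery by a
  Gaussian-convolved exponential fit.
* **tomography** — three-tube phantom, 512-element ring-array forward
  model (circular-mean projection) and backprojection, multiwavelength
  difference imaging, per-pixel nonnegative spectral unmixing, and
  noise-equivalent concentration (NEC = σ_c·c / c0,max).

## Worked example

```python
import numpy as np
from pppa import build_preset
from pppa.scan_analysis import run_pump_scan, run_delay_scan, fit_lifetime

katushka = build_preset("katushka")
mneptune = build_preset("mneptune")

scan_k = run_pump_scan(katushka)    # 500-660 nm, probe fixed at 650 nm
scan_n = run_pump_scan(mneptune)
print(f"TIDSA peak: Katushka {scan_k.peak_position:.0f} nm, "
      f"mNeptune {scan_n.peak_position:.0f} nm "
      f"(separation {scan_n.peak_position - scan_k.peak_position:.0f} nm)")

delays = np.arange(0.0, 10.5, 0.5)
fit = fit_lifetime(run_delay_scan(katushka, delays), pulse_fwhm_ns=3.0)
print(f"Katushka lifetime: {fit.tau_ns:.2f} +/- {fit.tau_stderr:.2f} ns "
      f"(preset value 2.0 ns)")
```

prints

```
TIDSA peak: Katushka 580 nm, mNeptune 605 nm (separation 25 nm)
Katushka lifetime: 1.91 +/- 0.12 ns (preset value 2.0 ns)
```

The pump-scan TIDSA spectra peak near each protein's absorption maximum
(588 and 608 nm; the few-nm offset is ground-state-depopulation bias at
12 mJ/cm²), and the two proteins are resolved by the blue shift of the
Katushka band.  The delay-scan fit recovers the generating excited-state
lifetime from the pulse-convolved decay to within 5 %.

A command-line interface mirrors the library
(`pppa scan|process|tomo-sim|reconstruct|unmix`), e.g.

```bash
pppa scan --protein mneptune --mode delay --fit-lifetime --out delay.csv
```

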