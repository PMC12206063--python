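name: mCardinal
lifetime_ns: 1.4
quantum_yield: 0.19
concentration_uM: 50.0
peak_extinction_M_cm: 87000.0
se_peak_ratio: 1.0
note: Synthetic surrogate spectra (Gaussian main band + vibronic shoulder); peak wavelengths,
  extinction, quantum yield are literature-typical values, not measured data.
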