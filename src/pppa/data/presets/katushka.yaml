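name: Katushka
lifetime_ns: 2.0
quantum_yield: 0.34
concentration_uM: 67.0
peak_extinction_M_cm: 65000.0
se_peak_ratio: 1.0
note: Synthetic surrogate spectra (Gaussian main band + vibronic shoulder); peak wavelengths,
  extinction, quantum yield are literature-typical values, not measured data.
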