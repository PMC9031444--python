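# Nine-peak spectral model for human subcutaneous fat.
# Offsets are chemical shift in ppm relative to water (4.7 ppm);
# amplitudes are relative proton fractions (renormalised on load).
# Edit freely — this table is configuration, not hard-coded truth.
peaks:
  - {offset_ppm: -3.80, amplitude: 0.088}   # CH3 methyl
  - {offset_ppm: -3.40, amplitude: 0.628}   # CH2 methylene (dominant)
  - {offset_ppm: -3.10, amplitude: 0.060}   # CH2 beta-carboxyl
  - {offset_ppm: -2.68, amplitude: 0.062}   # CH2 alpha-olefinic
  - {offset_ppm: -2.46, amplitude: 0.058}   # CH2 alpha-carboxyl
  - {offset_ppm: -1.95, amplitude: 0.006}   # CH2 diallylic
  - {offset_ppm: -0.50, amplitude: 0.039}   # glycerol CH2
  - {offset_ppm:  0.49, amplitude: 0.010}   # glycerol CH
  - {offset_ppm:  0.59, amplitude: 0.049}   # olefinic CH=CH
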