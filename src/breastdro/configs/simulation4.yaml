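# Simulator demonstration: complex white Gaussian noise calibrated to an
# image SNR of 30 (edit target_snr to 15 for the noisier variant or set
# noise to null for the noiseless reference).
seed: 44
output_dir: breastdro_out/simulation4
phantom:
  matrix: [64, 64, 32]
  fov_mm: [160.0, 160.0, 64.0]
  fibroglandular_fraction: 0.2
  skin_thickness_mm: 2.5
  smoothness_mm: 8.0
protocol:
  field_strength_T: 1.5
  tr_ms: 7.8
  flip_deg: 10.0
  te_ms: [2.2]
pattern:
  n_frames: 1
  ordering: centric
noise:
  target_snr: 30
recon: true
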