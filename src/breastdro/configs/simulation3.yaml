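# MRI-system demonstration: chemically selective fat saturation with a
# periodic 100-degree pulse repeated every 500 ms, at the 1.5 T
# opposed-phase echo time (2.2 ms; edit te_ms to 4.2 for in-phase).
seed: 33
output_dir: breastdro_out/simulation3
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
  fatsat:
    tr_ir_ms: 500.0
    alpha_ir_deg: 100.0
    formula: as_printed
pattern:
  n_frames: 1
  ordering: centric
noise: null
recon: true
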