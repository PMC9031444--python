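# Anatomy demonstration: synthetic bilateral breast phantom with skin,
# muscle and fibroglandular subtypes plus four concentric BPE levels.
# Desk scale (64x64x32) so it runs in seconds.
seed: 11
output_dir: breastdro_out/simulation1
phantom:
  matrix: [64, 64, 32]
  fov_mm: [160.0, 160.0, 64.0]
  fibroglandular_fraction: 0.2
  skin_thickness_mm: 2.5
  smoothness_mm: 8.0
bpe:
  category: moderate    # presets: minimal / mild / moderate / marked
  n_levels: 4
  quadrant_weight: 3.0
vif:
  kind: biexponential
  onset_min: 0.5
protocol:
  field_strength_T: 1.5
  tr_ms: 7.8
  flip_deg: 10.0
  te_ms: [2.2]
pattern:
  n_frames: 2
  ordering: centric
noise: null
recon: true
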