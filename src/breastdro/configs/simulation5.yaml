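# Temporal-resolution demonstration: a 2 cm spiculated lesion with a
# washout-enhancing rim (Ktrans = 0.5 /min, ve = 0.3) around a persistently
# enhancing core (Ktrans = 0.08 /min, ve = 0.4). Frames span 3.3 min each
# (199.68 s, the duration of a full 256x256x100 acquisition at TR 7.8 ms),
# realised on the desk-scale matrix by stretching the per-TR spacing.
# Set truth_mode: true for the instantaneous-acquisition gold standard, or
# frame_duration_s: 30 with n_frames: 40 for the accelerated-frame variant.
seed: 55
output_dir: breastdro_out/simulation5
phantom:
  matrix: [64, 64, 32]
  fov_mm: [160.0, 160.0, 64.0]
  fibroglandular_fraction: 0.2
  skin_thickness_mm: 2.5
  smoothness_mm: 8.0
vif:
  kind: biexponential
  onset_min: 1.0
lesions:
  - morphology: spiculated
    diameter_mm: 20.0
    rim_thickness_voxels: 1
    kinetics:
      rim:  {ktrans_per_min: 0.5,  ve: 0.3, vp: 0.0}
      core: {ktrans_per_min: 0.08, ve: 0.4, vp: 0.0}
protocol:
  field_strength_T: 1.5
  tr_ms: 7.8
  flip_deg: 10.0
  te_ms: [2.2]
pattern:
  n_frames: 6
  frame_duration_s: 199.68
  ordering: centric
truth_mode: false
noise: null
recon: true
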