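# Full-scale variant of simulation5: the conventional 256x256x100 encoding
# matrix at TR 7.8 ms (3.3 min per frame). SLOW: tens of minutes and
# several GB of k-space; use simulation5.yaml for desk-scale work.
seed: 55
output_dir: breastdro_out/simulation5_fullscale
phantom:
  matrix: [256, 256, 100]
  fov_mm: [320.0, 320.0, 160.0]
  fibroglandular_fraction: 0.2
  skin_thickness_mm: 2.0
  smoothness_mm: 8.0
vif:
  kind: biexponential
  onset_min: 1.0
lesions:
  - morphology: spiculated
    diameter_mm: 20.0
    rim_thickness_voxels: 2
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
  ordering: centric
truth_mode: false
noise: null
recon: false
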