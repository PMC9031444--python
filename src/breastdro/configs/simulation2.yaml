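# Physiology demonstration: the four BIRADS mass morphologies inserted with
# homogeneous enhancement (Ktrans = 0.08 /min, ve = 0.4, vp = 0).
seed: 22
output_dir: breastdro_out/simulation2
phantom:
  matrix: [64, 64, 32]
  fov_mm: [160.0, 160.0, 64.0]
  fibroglandular_fraction: 0.2
  skin_thickness_mm: 2.5
  smoothness_mm: 8.0
vif:
  kind: biexponential
  onset_min: 0.5
lesions:
  - morphology: round
    diameter_mm: 10.0
    center_voxel: [20, 35, 16]
    kinetics: {core: {ktrans_per_min: 0.08, ve: 0.4, vp: 0.0}}
  - morphology: lobulated
    diameter_mm: 12.5
    center_voxel: [44, 35, 16]
    kinetics: {core: {ktrans_per_min: 0.08, ve: 0.4, vp: 0.0}}
  - morphology: irregular
    diameter_mm: 12.5
    center_voxel: [20, 35, 10]
    kinetics: {core: {ktrans_per_min: 0.08, ve: 0.4, vp: 0.0}}
  - morphology: spiculated
    diameter_mm: 15.0
    center_voxel: [44, 35, 10]
    kinetics: {core: {ktrans_per_min: 0.08, ve: 0.4, vp: 0.0}}
protocol:
  field_strength_T: 1.5
  tr_ms: 7.8
  flip_deg: 10.0
  te_ms: [2.2]
pattern:
  n_frames: 3
  ordering: centric
noise: null
recon: true
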