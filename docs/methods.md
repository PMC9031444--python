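# Methods

`breastdro` synthesises dynamic contrast-enhanced (DCE) breast MRI k-space
data with known ground truth. This note records the models it implements,
the defaults it ships, the numerical choices behind them, and what the
synthetic phantom does and does not emulate.

## Anatomy model

The anatomy is organised as chemical-species *tissue classes* (fat, water)
on a shared voxel grid, axis order (x, y, z) = (medial–lateral,
posterior–anterior, inferior–superior), 0-based indices. Each class carries
a base image (equilibrium signal amplitude, arbitrary units), a spectral
model, and named *subtypes* — continuous partial-volume masks in [0, 1]
with per-subtype T1 (and optional T2*). Subtype masks partition their
class (voxelwise sum ≤ 1); the product `base_image × mask` is the subtype's
signal content, so a voxel can be a continuous mixture of fat and
fibroglandular tissue.

Default T1 values at 1.5 T (editable in `data/tissue_t1.yaml`): fat 296 ms,
skin 887 ms, chest-wall muscle 1130 ms, fibroglandular 1266 ms.

Water is on-resonance; fat uses a nine-peak subcutaneous-fat spectral model
(`data/fat_spectrum_subcutaneous_9peak.yaml`, offsets in ppm relative to
water, amplitudes renormalised on load). The dominant methylene peak at
−3.4 ppm (≈ −217 Hz at 1.5 T) reproduces the familiar 2.2 / 4.2 ms
opposed-/in-phase echo times and the dark-boundary ("India ink")
cancellation at mixed fat/water voxels.

### Background parenchymal enhancement (BPE)

A requested fraction (0–1) of fibroglandular voxels is drawn without
replacement, with upper-outer-quadrant voxels weighted `quadrant_weight`-fold
(default 3; the literature motivates preferential upper-outer involvement
but quantifies no weight, so this is a declared default). The quadrant is
determined per breast side by splitting each side's mask at its centroid
along the superior/inferior and medial/lateral axes. The selected set is
split into `n_levels` concentric shells by erosion depth (chessboard
distance), innermost shell = highest enhancement level. Clinical BPE grades
map to preset fractions minimal = 0.10, mild = 0.25, moderate = 0.50,
marked = 0.75 — presets only, fully overridable. Selection is deterministic
given the seed.

## Synthetic phantom

Because the anatomy loader normally consumes separated fat/water volumes
from a chemical-shift-encoded exam, the package ships a procedural
generator so every module is testable without image data: bilateral
semi-ellipsoidal breasts attached to a posterior muscle slab, a skin shell
(default 2.5 mm) obtained by erosion, and a fibroglandular compartment
generated by thresholding a Gaussian random field smoothed to
`smoothness_mm` (default 8 mm), biased toward the central breast, with a
sigmoid transition providing continuous partial volume. The threshold is
the field quantile that realises the target fibroglandular fraction
(default 0.2 of the breast volume; realised within ±0.05 across seeds).
Default grid 64 × 64 × 32 over 160 × 160 × 64 mm so a full dynamic
simulation runs in seconds.

The phantom emulates the *statistical* roles that matter to k-space
synthesis — tissue-class partitioning, partial volume, a heterogeneous
fibroglandular distribution, plausible geometry. It does not emulate real
anatomical texture, ductal structure, vascularity, or visual realism:
passing tests demonstrate the correctness of the simulation machinery, not
that reconstructions of real breasts will look like these volumes.

## Lesions

The four mass-morphology classes of the BIRADS lexicon are generated from
unions of randomly placed overlapping spheres: *round* (few, tightly
clustered), *lobulated* (few large, offset), *irregular* (many small,
wide jitter), *spiculated* (compact core plus tapering conical spicules
with random orientations; count and length configurable). Sphere counts
and jitter radii are documented defaults, not derived quantities. The
geometry is scaled analytically so the union's longest extent equals the
requested diameter, then corrected once against the measured extent of the
digitised support (digitisation shrinks thin features such as spicule
tips); the result is within one voxel of the request. Spicule radii are
floored at 0.55 × the largest voxel dimension so they stay resolvable.

Enhancement heterogeneity: *rim enhancement* splits the lesion into a core
(binary support eroded `rim_thickness` times, 6-connected) and rim
(remainder); *pseudo-random heterogeneity* partitions lesion voxels among
labelled subtypes at given fractions. Insertion replaces the water base
image inside the lesion with i.i.d. Gaussian values (clipped at zero)
matching the mean and SD of the fibroglandular region, zeroes the fat
content there (lesions displace fat and may extend into it), carves the
lesion out of existing water subtypes, and registers each lesion subtype
with its kinetic parameters.

## Kinetics

Tissue concentration follows the three-parameter generalized kinetic
(Tofts) model

    Ct(t) = Ktrans (Cp ⊗ e^(−kep t))(t) + vp Cp(t),  kep = Ktrans/ve.

The convolution is evaluated on a uniform internal grid of 0.1 s with
trapezoidal weights (O(dt²)); halving the step changes outputs by < 0.1%
(measured ~1e-9 relative against the closed-form biexponential solution),
then linearly interpolated to the requested times. The default vascular
input is a Weinmann-type biexponential population function
(dose 0.1 mmol/kg, a₁ = 3.99, a₂ = 4.78 kg/L, m₁ = 0.144, m₂ = 0.0111
min⁻¹); a Parker population function and tabulated inputs are selectable.
Any causal nonnegative Cp exercises the machinery identically, so results
that matter here (parameter recovery, temporal-averaging behaviour) do not
depend on the input's exact shape. `fit_gkm` provides the companion
nonlinear least-squares recovery (trust-region reflective, neutral start
(0.1, 0.3), bounds ktrans ≥ 0, ve ∈ (0, 1]); non-convergence is flagged,
never silent.

## MRI system

Steady-state spoiled gradient echo, ignoring T2*:

    S = S0 sin α (1 − E)/(1 − E cos α),  E = e^(−TR/T1).

Chemically selective fat saturation (periodic pulse, repetition TRIR, flip
αIR, steady state, small imaging flip) uses the pre-pulse equilibrium
MzEq = (1 − EIR)/(1 − EIR cos αIR) and a recovery factor applied to the fat
signal at time t after the pulse, evaluated **per sample** at the sample's
absolute time modulo TRIR. Two recovery variants ship:

* `as_printed` (default): Mz(t) = 1 − MzEq cos αIR e^(−t/T1) — a compact
  form that drops a term of the full solution. Note that for
  αIR > 90° this expression gives Mz ≥ 1 at all t, i.e. no suppression.
* `standard_ir`: Mz(t) = 1 − (1 − MzEq cos αIR) e^(−t/T1) — the textbook
  inversion-recovery solution, which does suppress (fat ROI magnitude
  ratio ≈ 0.54 at 100°/500 ms on the desk phantom). Behavioural tests of
  suppression use this variant.

Contrast maps to signal through r1 relaxivity (default 4.5 s⁻¹mM⁻¹,
typical of gadobutrol-class agents at 1.5 T): 1/T1(t) = 1/T1₀ + r1·Ct, and
the multiplicative k-space weight is SPGR(T1(t))/SPGR(T1₀). Users may
instead supply enhancement curves directly as weights. The spectral weight
of a class at echo time TE is Σₚ aₚ e^(i2πΔfₚTE), Δfₚ = ppmₚ · 42.577 MHz/T
· B0.

Sampling patterns pair k-space coordinates (cycles/FOV, DC centred,
Cartesian integers in [−N/2, N/2)) with a per-TR timing vector. The
rectilinear builder assigns one TR per (ky, kz) phase-encode pair with the
readout fully sampled per TR; sample time = TR start + TE. Orderings:
`sequential` (raster) and `centric` (default) — low-frequency encodes
scheduled at the temporal centre of the frame, so the k-space centre is
acquired when a suitably timed enhancement peak occurs. Coil maps are
smooth loop-like complex profiles (1/distance falloff from anterior
positions) with strictly positive root-sum-of-squares.

## Simulator

Per frame and channel, each subtype is processed independently: static
image-space weighting (base × mask × SPGR(T1), × coil map), one Fourier
transform (centred FFT on-grid; an exact chunked non-uniform DFT
off-grid — exact rather than approximate gridding, affordable at desk
scale), then per-sample dynamic complex weights (spectral precession,
fat-sat recovery, enhancement at the sample's absolute time — or at the
frame-centre time in *truth mode* — and optional e^(−TE/T2*), off by
default). Subtype transforms are cached across frames that share
coordinates, so a 40-frame dynamic run costs one FFT per subtype. Because
enhancement varies over minutes, it is evaluated at TR start + TE;
spectral and fat-sat weights use exact intra-TR offsets. Contributions are
summed over subtypes and classes; ground truth (per-subtype concentration
and enhancement at frame centres, subtype masks) is always emitted.

**Noise and SNR.** SNR is defined as mean magnitude over the breast mask
of the noiseless reconstruction divided by the per-pixel noise SD of one
real channel in the reconstructed image. For a fully sampled Cartesian
frame with the unnormalised inverse FFT over Nvox voxels, k-space noise of
per-component SD σ maps to image noise σ/√Nvox, so the injected SD is
σ = √Nvox · mean/SNR. The measurement utility reads the noise SD from the
real channel of a signal-free region for complex images, or from the
background magnitude divided by √(2 − π/2) (Rayleigh correction) for
magnitude images.

## Reference reconstruction

A centred inverse FFT (Cartesian) or adjoint non-uniform DFT (off-grid,
best-effort, with a warning) plus root-sum-of-squares coil combination —
verification tools only; accelerated reconstructions are deliberately out
of scope, since the simulator exists to generate test data for them.

## Experiment runner and provenance

YAML configs describe the full pipeline; one global seed derives per-stage
seeds by seed-sequence spawning so streams are independent and
reproducible, and every output carries the config hash and seed. Bundled
desk-scale configs demonstrate: BPE levels (`simulation1`), the four
lesion morphologies with homogeneous enhancement Ktrans = 0.08 min⁻¹,
ve = 0.4 (`simulation2`), fat saturation at 100°/500 ms and the 1.5 T
two-echo TEs 2.2/4.2 ms (`simulation3`), noise at SNR 30/15
(`simulation4`), and temporal averaging with a 2 cm spiculated rim lesion —
washout rim Ktrans = 0.5 min⁻¹, ve = 0.3 around a persistent core
Ktrans = 0.08 min⁻¹, ve = 0.4 (`simulation5`). The conventional 3.3-min
frame (256 × 256 × 100 encodes at TR 7.8 ms = 199.68 s) is realised at
desk scale by stretching the TR so the 64 × 64 × 32 frame spans the same
duration, preserving the temporal-averaging physics at a tractable size; a
full-scale config is included and marked slow. In the bundled temporal
experiment, frame-averaged acquisition underestimates the peak rim signal
relative to truth mode, and 30-s frames reduce the rim-curve RMSE by more
than an order of magnitude.

## Known limitations

B0/B1 inhomogeneity, patient motion, gradient/RF imperfections and eddy
currents are not modelled (dynamic processing is multiplicative in k-space
per tissue, which precludes efficient spatially varying off-resonance).
Lesions are stylised spatial-frequency content, not reader-study-realistic
textures. Noise calibration assumes a fully sampled Cartesian frame for
the noiseless reference (non-Cartesian calibration falls back to the
adjoint). The SNR definition above is a package convention; magnitude bias
at low SNR is handled only through the documented Rayleigh correction.
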