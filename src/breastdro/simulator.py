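"""k-space synthesis engine.

Per time frame and channel, each tissue subtype is processed independently:

1. static image-space weighting — base image x subtype mask x steady-state
   SPGR signal for the subtype's T1 (and the coil sensitivity, if present);
2. Fourier transform to the sampling pattern's k-space locations (centred
   FFT on a Cartesian grid, exact non-uniform DFT off-grid), computed once
   per subtype and reused across frames sharing the same coordinates;
3. dynamic complex weighting per sample — spectral precession of the
   subtype's chemical species at the sample TE, fat-saturation recovery at
   the time since the last saturation pulse, the subtype's contrast
   enhancement factor at the sample's absolute acquisition time (or at the
   frame-centre time in truth mode), and optional T2* decay;
4. recombination over subtypes and classes, plus calibrated complex white
   Gaussian noise per channel.

Because each subtype's spatial content is static, dynamic processes act as
multiplicative k-space weights; this is what makes simulating a multi-minute
DCE acquisition with per-TR timing affordable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anatomy import AnatomyModel, TissueClass, TissueSubtype
from .fourier import inverse_cartesian, kspace_at, samples_to_grid
from .kinetics import VascularInputFunction, gkm_concentration
from .mri import (
    CoilSensitivities,
    SamplingPattern,
    ScanProtocol,
    enhancement_signal_scale,
    fatsat_mz_eq,
    fatsat_mz_t,
    spectral_weight,
    spgr_signal,
)

__all__ = [
    "NoiseSpec",
    "SimulationJob",
    "KSpaceDataset",
    "static_image_weighting",
    "tissue_kspace",
    "apply_dynamic_weights",
    "combine_and_add_noise",
    "simulate",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Complex white Gaussian noise calibrated to a target image SNR.

    SNR is defined as mean magnitude over the breast-tissue mask of the
    noiseless reconstruction divided by the per-pixel noise SD of one real
    channel in the reconstructed image.
    """

    target_snr: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.target_snr > 0):
            raise ValueError("target_snr must be positive")


@dataclass
class SimulationJob:
    """Everything needed to synthesise one dynamic k-space dataset."""

    anatomy: AnatomyModel
    protocol: ScanProtocol
    frames: list[SamplingPattern]
    vif: VascularInputFunction | None = None
    coils: CoilSensitivities | None = None
    noise: NoiseSpec | None = None
    truth_mode: bool = False

    def validate(self) -> "SimulationJob":
        self.anatomy.validate()
        if not self.frames:
            raise ValueError("job needs at least one frame pattern")
        if self.coils is not None and self.coils.maps.shape[1:] != self.anatomy.grid.matrix_size:
            raise ValueError("coil maps do not match the anatomy grid")
        ends = [p.tr_start_times_s[0] for p in self.frames]
        if np.any(np.diff(ends) < 0):
            raise ValueError("frames must be ordered in time")
        has_kinetics = any(
            st.kinetic_params is not None for _, st in self.anatomy.iter_subtypes()
        )
        if has_kinetics and self.vif is None:
            raise ValueError("subtypes carry kinetic parameters but no VIF is set")
        return self

    @property
    def n_channels(self) -> int:
        return self.coils.n_channels if self.coils is not None else 1

    def frame_center_time_s(self, f: int) -> float:
        p = self.frames[f]
        start = p.tr_start_times_s[0]
        end = p.tr_start_times_s[-1] + p.tr_ms / 1000.0
        return 0.5 * (start + end)


@dataclass
class KSpaceDataset:
    """Simulator output: per-frame, per-channel complex samples aligned 1:1
    with the sampling pattern, plus ground-truth record and metadata."""

    frames: list[np.ndarray]  # each (n_channels, n_samples) complex
    patterns: list[SamplingPattern]
    truth: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def to_hdf5(self, path) -> None:
        import h5py
        import yaml

        with h5py.File(path, "w") as h5:
            for f, (data, pat) in enumerate(zip(self.frames, self.patterns)):
                g = h5.create_group(f"kspace/frame{f}")
                for c in range(data.shape[0]):
                    g.create_dataset(f"channel{c}", data=data[c].astype(np.complex64))
                pg = h5.create_group(f"pattern/frame{f}")
                pg.create_dataset("coords", data=pat.coords.astype(np.float32))
                pg.create_dataset("tr_index", data=pat.tr_index.astype(np.int32))
                pg.create_dataset("times", data=pat.sample_times_s.astype(np.float64))
                pg.attrs["tr_ms"] = pat.tr_ms
                pg.attrs["cartesian"] = pat.cartesian
                if pat.matrix is not None:
                    pg.attrs["matrix"] = pat.matrix
            tg = h5.create_group("truth")
            for key, val in self.truth.items():
                tg.create_dataset(key, data=np.asarray(val))
            h5.create_group("meta").attrs["yaml"] = yaml.safe_dump(self.meta)


def static_image_weighting(job: SimulationJob) -> dict[str, np.ndarray]:
    """Per-subtype pre-contrast images: base x mask x SPGR(T1) (x coil map).

    Returns a map from subtype key to an array of shape
    (n_channels, nx, ny, nz); single-channel jobs have one uniform channel.
    """
    out: dict[str, np.ndarray] = {}
    proto = job.protocol
    for cls, st in job.anatomy.iter_subtypes():
        if st.t1_ms is None or st.t1_ms <= 0:
            raise ValueError(f"subtype '{st.name}' has no valid T1")
        w = spgr_signal(1.0, proto.flip_deg, proto.tr_ms, st.t1_ms)
        img = cls.base_image * st.mask * w
        if job.coils is not None:
            out[f"{cls.name}/{st.name}"] = job.coils.maps * img[None, ...]
        else:
            out[f"{cls.name}/{st.name}"] = img[None, ...].astype(complex)
    return out


def tissue_kspace(image: np.ndarray, pattern: SamplingPattern) -> np.ndarray:
    """Fourier samples of one (complex) image at the pattern's coordinates."""
    return kspace_at(image, pattern.coords, pattern.cartesian)


def _subtype_dynamic_weights(
    cls: TissueClass,
    st: TissueSubtype,
    pattern: SamplingPattern,
    job: SimulationJob,
    frame: int,
) -> np.ndarray:
    proto = job.protocol
    te_ms = pattern.intra_tr_offset_s * 1000.0
    w = spectral_weight(cls.spectral_model, te_ms, proto.field_strength_T)
    w = np.asarray(w, dtype=complex) * np.ones(pattern.n_samples, dtype=complex)

    if proto.fatsat is not None and cls.name == "fat":
        fs = proto.fatsat
        mz_eq = fatsat_mz_eq(fs.tr_ir_ms, st.t1_ms, fs.alpha_ir_deg)
        t_pulse_ms = np.mod(pattern.sample_times_s * 1000.0, fs.tr_ir_ms)
        w = w * fatsat_mz_t(mz_eq, fs.alpha_ir_deg, t_pulse_ms, st.t1_ms, fs.formula)

    if st.kinetic_params is not None:
        if job.truth_mode:
            t_min = np.full(pattern.n_samples, job.frame_center_time_s(frame) / 60.0)
        else:
            t_min = pattern.sample_times_s / 60.0
        ct = gkm_concentration(st.kinetic_params, job.vif, np.sort(t_min))
        ct = ct[np.argsort(np.argsort(t_min))]  # undo the sort for evaluation
        w = w * enhancement_signal_scale(ct, st.t1_ms, proto)

    if st.t2_ms is not None:
        w = w * np.exp(-te_ms / st.t2_ms)
    return w


def apply_dynamic_weights(
    samples: np.ndarray,
    cls: TissueClass,
    st: TissueSubtype,
    pattern: SamplingPattern,
    job: SimulationJob,
    frame: int = 0,
) -> np.ndarray:
    """Multiply static k-space samples by the subtype's dynamic weights:
    spectral precession, fat saturation, contrast enhancement, T2* decay."""
    if samples.shape[-1] != pattern.n_samples:
        raise ValueError("samples must align with the pattern")
    return samples * _subtype_dynamic_weights(cls, st, pattern, job, frame)


def _noise_sigma_k(job: SimulationJob, frame_data: np.ndarray, pattern: SamplingPattern) -> float:
    """k-space noise SD (per real component) realising the target image SNR.

    Uses the noiseless reconstruction of channel 0: with an unnormalised
    inverse FFT over Nvox voxels, k-space noise of SD sigma_k maps to image
    noise of SD sigma_k / sqrt(Nvox) per real component.
    """
    matrix = pattern.matrix or job.anatomy.grid.matrix_size
    if pattern.cartesian:
        img = inverse_cartesian(samples_to_grid(frame_data[0], pattern.coords, matrix))
    else:  # best effort for non-Cartesian calibration
        from .fourier import adjoint_nudft

        img = adjoint_nudft(frame_data[0], pattern.coords, matrix)
    mask = job.anatomy.breast_mask()
    mean_tissue = float(np.abs(img)[mask].mean())
    if mean_tissue == 0:
        raise ValueError("cannot calibrate noise: breast signal is zero")
    n_vox = float(np.prod(matrix))
    return mean_tissue / job.noise.target_snr * np.sqrt(n_vox)


def combine_and_add_noise(
    per_subtype: dict[str, np.ndarray],
    job: SimulationJob,
    pattern: SamplingPattern,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sum subtype k-space contributions and add calibrated complex noise.

    Without a noise spec the output is exactly the sum of the inputs.
    Noise is i.i.d. complex Gaussian, independent per channel, deterministic
    given the noise seed.
    """
    data = None
    for arr in per_subtype.values():
        data = arr.copy() if data is None else data + arr
    if data is None:
        raise ValueError("no subtype data to combine")
    if job.noise is not None and np.isfinite(job.noise.target_snr):
        sigma = _noise_sigma_k(job, data, pattern)
        if rng is None:
            rng = np.random.default_rng(job.noise.seed)
        noise = rng.normal(0.0, sigma, size=data.shape) + 1j * rng.normal(
            0.0, sigma, size=data.shape
        )
        data = data + noise
    return data


def simulate(job: SimulationJob) -> KSpaceDataset:
    """Run the full pipeline over every frame and channel.

    The static Fourier transform of each subtype is computed once and
    reused across frames that share sampling coordinates. Ground truth
    (per-subtype enhancement factors at frame centres, subtype masks for
    enhancing subtypes) is always emitted alongside the k-space data.
    """
    job.validate()
    weighted = static_image_weighting(job)
    rng = np.random.default_rng(job.noise.seed) if job.noise is not None else None

    static_cache: dict[tuple[str, int], np.ndarray] = {}
    cache_coords: np.ndarray | None = None
    frames_out = []
    for f, pattern in enumerate(job.frames):
        if cache_coords is None or not np.array_equal(cache_coords, pattern.coords):
            static_cache.clear()
            cache_coords = pattern.coords
        per_subtype: dict[str, np.ndarray] = {}
        for cls, st in job.anatomy.iter_subtypes():
            key = f"{cls.name}/{st.name}"
            chans = []
            for c in range(job.n_channels):
                ck = (key, c)
                if ck not in static_cache:
                    static_cache[ck] = tissue_kspace(weighted[key][c], pattern)
                chans.append(static_cache[ck])
            arr = np.stack(chans)
            per_subtype[key] = apply_dynamic_weights(arr, cls, st, pattern, job, f)
        frames_out.append(combine_and_add_noise(per_subtype, job, pattern, rng))

    truth = _ground_truth(job)
    meta = {
        "protocol": {
            "field_strength_T": job.protocol.field_strength_T,
            "tr_ms": job.protocol.tr_ms,
            "flip_deg": job.protocol.flip_deg,
            "te_ms": list(job.protocol.te_ms),
        },
        "truth_mode": job.truth_mode,
        "n_channels": job.n_channels,
        "noise_seed": None if job.noise is None else job.noise.seed,
        "software": "breastdro 0.1.0",
    }
    return KSpaceDataset(frames=frames_out, patterns=list(job.frames), truth=truth, meta=meta)


def _ground_truth(job: SimulationJob) -> dict:
    centers_s = np.array([job.frame_center_time_s(f) for f in range(len(job.frames))])
    truth: dict[str, np.ndarray] = {"frame_center_times_s": centers_s}
    for cls, st in job.anatomy.iter_subtypes():
        if st.kinetic_params is None:
            continue
        ct = gkm_concentration(st.kinetic_params, job.vif, centers_s / 60.0)
        truth[f"ct_mM/{cls.name}/{st.name}"] = ct
        truth[f"enhancement/{cls.name}/{st.name}"] = np.asarray(
            enhancement_signal_scale(ct, st.t1_ms, job.protocol)
        )
        truth[f"mask/{cls.name}/{st.name}"] = st.mask
    return truth
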