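"""MRI system model: signal equations, protocol, sampling, coils.

The steady-state spoiled-gradient-echo (SPGR) magnitude signal is

    S = S0 sin(a) (1 - E) / (1 - E cos(a)),   E = exp(-TR/T1),

ignoring T2* effects. Chemically selective fat saturation with a periodic
inversion pulse (repetition TRIR, flip aIR) is modelled in the small-flip,
steady-state limit by the pre-pulse equilibrium magnetisation

    MzEq = (1 - EIR) / (1 - EIR cos(aIR)),    EIR = exp(-TRIR/T1),

and a recovery factor applied to the fat signal at time t after the pulse.
Two recovery variants are exposed: ``as_printed`` (the compact form
Mz(t) = 1 - MzEq cos(aIR) e^(-t/T1), which drops a term relative to the
full inversion-recovery solution) and ``standard_ir``
(Mz(t) = 1 - (1 - MzEq cos(aIR)) e^(-t/T1), the textbook inversion-recovery
solution). The default is ``as_printed``.

Gadolinium enhancement maps to signal through r1 relaxivity:
1/T1(t) = 1/T1_base + r1 Ct(t), and the multiplicative k-space weight is
the ratio of SPGR signals at T1(t) and T1_base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .grid import VoxelGrid
from .spectral import SpectralModel

__all__ = [
    "GAMMA_MHZ_PER_T",
    "ScanProtocol",
    "FatSatSettings",
    "SamplingPattern",
    "CoilSensitivities",
    "spgr_signal",
    "fit_spgr_t1",
    "fatsat_mz_eq",
    "fatsat_mz_t",
    "enhancement_signal_scale",
    "spectral_weight",
    "build_cartesian_pattern",
    "frame_duration",
    "simulate_coil_maps",
]

#: Gyromagnetic ratio of the proton, MHz/T.
GAMMA_MHZ_PER_T = 42.577


@dataclass(frozen=True)
class FatSatSettings:
    tr_ir_ms: float
    alpha_ir_deg: float
    formula: str = "as_printed"

    def __post_init__(self) -> None:
        if self.tr_ir_ms <= 0:
            raise ValueError("tr_ir_ms must be positive")
        if self.formula not in ("as_printed", "standard_ir"):
            raise ValueError(f"unknown fat-sat formula '{self.formula}'")


@dataclass(frozen=True)
class ScanProtocol:
    """Acquisition settings for one simulated scan."""

    field_strength_T: float = 1.5
    tr_ms: float = 7.8
    flip_deg: float = 10.0
    te_ms: tuple[float, ...] = (2.2,)
    r1_relaxivity_per_mM_per_s: float = 4.5
    fatsat: FatSatSettings | None = None
    bandwidth_hz: float | None = None

    def __post_init__(self) -> None:
        te = self.te_ms if isinstance(self.te_ms, (tuple, list)) else (self.te_ms,)
        object.__setattr__(self, "te_ms", tuple(float(t) for t in te))
        if self.field_strength_T <= 0 or self.tr_ms <= 0:
            raise ValueError("field strength and TR must be positive")
        if not (0.0 < self.flip_deg <= 90.0):
            raise ValueError("flip_deg must be in (0, 90]")
        if any(t <= 0 for t in self.te_ms):
            raise ValueError("all echo times must be positive")
        if self.tr_ms <= max(self.te_ms):
            raise ValueError("TR must exceed the longest TE")
        if self.r1_relaxivity_per_mM_per_s < 0:
            raise ValueError("relaxivity must be nonnegative")


def spgr_signal(s0, flip_deg, tr_ms, t1_ms):
    """Steady-state SPGR magnitude signal (T2* ignored). Vectorised."""
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("t1_ms must be positive")
    if np.any(np.asarray(tr_ms) <= 0):
        raise ValueError("tr_ms must be positive")
    a = np.deg2rad(flip_deg)
    e1 = np.exp(-np.asarray(tr_ms, dtype=float) / t1)
    return s0 * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


def fit_spgr_t1(signals, flip_deg, tr_ms, x0=(1.0, 1000.0)):
    """Fit (S0, T1 ms) to variable-flip-angle SPGR signals by least squares."""
    signals = np.asarray(signals, dtype=float)
    flips = np.asarray(flip_deg, dtype=float)
    if signals.shape != flips.shape:
        raise ValueError("signals and flip angles must align")

    def residuals(x):
        return spgr_signal(x[0], flips, tr_ms, x[1]) - signals

    res = optimize.least_squares(
        residuals, x0, bounds=([0.0, 1.0], [np.inf, 1e5]), xtol=1e-14, ftol=1e-14
    )
    return {"s0": float(res.x[0]), "t1_ms": float(res.x[1]), "converged": bool(res.success)}


def fatsat_mz_eq(tr_ir_ms, t1_ms, alpha_ir_deg):
    """Equilibrium longitudinal magnetisation before each saturation pulse."""
    if tr_ir_ms <= 0 or np.any(np.asarray(t1_ms) <= 0):
        raise ValueError("times must be positive")
    e = np.exp(-tr_ir_ms / np.asarray(t1_ms, dtype=float))
    return (1.0 - e) / (1.0 - e * np.cos(np.deg2rad(alpha_ir_deg)))


def fatsat_mz_t(mz_eq, alpha_ir_deg, t_since_pulse_ms, t1_ms, formula="as_printed"):
    """Longitudinal fat magnetisation at time t after the saturation pulse.

    Applied as a multiplicative scale on the SPGR fat signal. See the module
    docstring for the two formula variants.
    """
    t = np.asarray(t_since_pulse_ms, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_pulse_ms must be >= 0")
    decay = np.exp(-t / t1_ms)
    mz0 = mz_eq * np.cos(np.deg2rad(alpha_ir_deg))
    if formula == "as_printed":
        return 1.0 - mz0 * decay
    if formula == "standard_ir":
        return 1.0 - (1.0 - mz0) * decay
    raise ValueError(f"unknown fat-sat formula '{formula}'")


def enhancement_signal_scale(ct_mM, t1_base_ms, protocol: ScanProtocol):
    """Multiplicative signal enhancement factor for concentration Ct.

    1/T1(t) = 1/T1_base + r1 Ct (rates in 1/s); returns
    SPGR(T1(t)) / SPGR(T1_base). Vectorised over Ct.
    """
    ct = np.asarray(ct_mM, dtype=float)
    if np.any(ct < 0):
        raise ValueError("Ct must be nonnegative")
    r1 = protocol.r1_relaxivity_per_mM_per_s
    if r1 < 0:
        raise ValueError("relaxivity must be nonnegative")
    rate_s = 1.0 / (t1_base_ms / 1000.0) + r1 * ct
    t1_ms = 1000.0 / rate_s
    base = spgr_signal(1.0, protocol.flip_deg, protocol.tr_ms, t1_base_ms)
    return spgr_signal(1.0, protocol.flip_deg, protocol.tr_ms, t1_ms) / base


def spectral_weight(model: SpectralModel, te_ms, field_T) -> complex:
    """Complex precession weight of a spectral model at echo time TE.

    sum_p a_p exp(i 2 pi df_p TE) with df_p = offset_ppm * gamma * B0.
    Modulus <= 1 with equality iff all peaks are in phase.
    """
    te_s = np.asarray(te_ms, dtype=float) * 1e-3
    if np.any(te_s < 0):
        raise ValueError("te_ms must be >= 0")
    w = np.zeros(np.shape(te_s), dtype=complex)
    for ppm, amp in model.peaks:
        df_hz = ppm * GAMMA_MHZ_PER_T * 1e6 * field_T * 1e-6
        w = w + amp * np.exp(2j * np.pi * df_hz * te_s)
    return complex(w) if w.ndim == 0 else w


@dataclass
class SamplingPattern:
    """k-space sample locations paired with a per-TR timing vector.

    coords are in cycles/FOV (integers on the Cartesian grid, DC at index 0
    after centring, stored in the range [-N/2, N/2)); each sample maps to
    exactly one TR via ``tr_index`` and carries an intra-TR offset (its TE).
    """

    coords: np.ndarray  # (N, 3) float
    tr_start_times_s: np.ndarray  # (n_tr,)
    tr_index: np.ndarray  # (N,) int
    intra_tr_offset_s: np.ndarray  # (N,)
    tr_ms: float
    cartesian: bool = True
    matrix: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.tr_start_times_s = np.asarray(self.tr_start_times_s, dtype=float)
        self.tr_index = np.asarray(self.tr_index, dtype=np.int64)
        self.intra_tr_offset_s = np.asarray(self.intra_tr_offset_s, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if np.any(np.diff(self.tr_start_times_s) < 0):
            raise ValueError("tr_start_times must be nondecreasing")
        if self.tr_index.shape[0] != self.coords.shape[0]:
            raise ValueError("tr_index must align with coords")
        if np.any(self.tr_index < 0) or np.any(self.tr_index >= self.tr_start_times_s.size):
            raise ValueError("every sample must map to exactly one TR")
        if self.cartesian and not np.allclose(self.coords, np.round(self.coords)):
            raise ValueError("Cartesian coords must lie on the integer grid")

    @property
    def n_samples(self) -> int:
        return self.coords.shape[0]

    @property
    def sample_times_s(self) -> np.ndarray:
        """Absolute time of each sample: its TR start plus intra-TR offset."""
        return self.tr_start_times_s[self.tr_index] + self.intra_tr_offset_s


@dataclass
class CoilSensitivities:
    """Per-channel complex sensitivity maps on the grid."""

    maps: np.ndarray  # (n_channels, nx, ny, nz) complex

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=complex)
        if self.maps.ndim != 4 or self.maps.shape[0] < 1:
            raise ValueError("maps must be (n_channels, nx, ny, nz) with >= 1 channel")

    @property
    def n_channels(self) -> int:
        return self.maps.shape[0]


def _centric_order(n_pe: int, radii: np.ndarray) -> np.ndarray:
    """Order phase encodes so the lowest spatial frequencies fall at the
    temporal centre of the frame and the highest at its edges."""
    by_radius = np.argsort(radii, kind="stable")[::-1]  # high freq first
    order = np.empty(n_pe, dtype=np.int64)
    front, back = 0, n_pe - 1
    for i, idx in enumerate(by_radius):
        if i % 2 == 0:
            order[front] = idx
            front += 1
        else:
            order[back] = idx
            back -= 1
    return order


def build_cartesian_pattern(
    matrix: tuple[int, int, int],
    tr_ms: float,
    te_ms: float,
    frame_start_s: float = 0.0,
    ordering: str = "centric",
) -> SamplingPattern:
    """Rectilinear Cartesian pattern: one TR per (ky, kz) phase-encode pair,
    readout (kx) fully sampled within each TR.

    ``ordering``: 'centric' (default) schedules low-frequency phase encodes
    at the temporal centre of the frame; 'sequential' is raster order.
    Sample time = TR start + TE.
    """
    nx, ny, nz = (int(m) for m in matrix)
    if min(nx, ny, nz) < 1:
        raise ValueError("matrix must be positive")
    if ordering not in ("sequential", "centric"):
        raise ValueError(f"unknown ordering '{ordering}'")
    ky, kz = np.meshgrid(
        np.arange(ny) - ny // 2, np.arange(nz) - nz // 2, indexing="ij"
    )
    ky = ky.ravel()
    kz = kz.ravel()
    n_pe = ky.size
    if ordering == "centric":
        order = _centric_order(n_pe, np.hypot(ky, kz))
        ky, kz = ky[order], kz[order]

    kx = np.arange(nx) - nx // 2
    coords = np.empty((n_pe * nx, 3))
    coords[:, 0] = np.tile(kx, n_pe)
    coords[:, 1] = np.repeat(ky, nx)
    coords[:, 2] = np.repeat(kz, nx)
    tr_start = frame_start_s + np.arange(n_pe) * (tr_ms / 1000.0)
    tr_index = np.repeat(np.arange(n_pe), nx)
    offsets = np.full(n_pe * nx, te_ms / 1000.0)
    return SamplingPattern(
        coords=coords,
        tr_start_times_s=tr_start,
        tr_index=tr_index,
        intra_tr_offset_s=offsets,
        tr_ms=tr_ms,
        cartesian=True,
        matrix=(nx, ny, nz),
    )


def frame_duration(pattern: SamplingPattern) -> float:
    """Total acquisition time in seconds: last TR start + TR - first TR start."""
    if pattern.tr_start_times_s.size == 0:
        raise ValueError("pattern has no TRs")
    return float(
        pattern.tr_start_times_s[-1] + pattern.tr_ms / 1000.0 - pattern.tr_start_times_s[0]
    )


def simulate_coil_maps(grid: VoxelGrid, n_channels: int, geometry_seed: int = 0) -> CoilSensitivities:
    """Smooth loop-coil-like complex sensitivity maps.

    Channels are placed around the anterior surface; each map has a
    1/distance falloff and a smooth phase, so the root-sum-of-squares is
    strictly positive over the volume. Deterministic given the seed.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    rng = np.random.default_rng(geometry_seed)
    x, y, z = grid.coordinates_mm()
    fx, fy, fz = grid.fov_mm
    maps = np.empty((n_channels,) + grid.matrix_size, dtype=complex)
    for c in range(n_channels):
        ang = 2 * np.pi * c / n_channels + rng.uniform(-0.2, 0.2)
        cx = 0.65 * fx / 2 * np.cos(ang)
        cz = 0.65 * fz / 2 * np.sin(ang)
        cy = fy / 2 * 1.1  # anterior of the volume
        d = np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)
        r0 = 0.35 * max(fx, fy, fz)
        mag = r0 / (r0 + d)
        phase = 2 * np.pi * (0.1 * (x - cx) / fx + 0.1 * (z - cz) / fz) + rng.uniform(0, 2 * np.pi)
        maps[c] = mag * np.exp(1j * phase)
    return CoilSensitivities(maps=maps)
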