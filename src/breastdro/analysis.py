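"""Reference reconstruction and measurement utilities.

These are verification tools, not the accelerated reconstructions the
simulated data are meant to stress-test: a centred inverse FFT (Cartesian)
or adjoint non-uniform DFT (off-grid), root-sum-of-squares coil
combination, and an SNR meter with Rayleigh background correction.
"""

from __future__ import annotations

import warnings

import numpy as np

from .fourier import adjoint_nudft, inverse_cartesian, samples_to_grid
from .simulator import KSpaceDataset

__all__ = ["reference_recon", "rss_combine", "measure_snr"]

#: Rayleigh SD correction: background magnitude of complex Gaussian noise of
#: per-component SD sigma has SD sigma*sqrt(2 - pi/2).
RAYLEIGH_SD_FACTOR = float(np.sqrt(2.0 - np.pi / 2.0))


def reference_recon(dataset: KSpaceDataset, matrix=None) -> list[np.ndarray]:
    """Reconstruct each frame; multi-coil data combined by root-sum-of-squares.

    Returns one volume per frame: complex for single-channel data (so phase
    information survives), real RSS magnitude for multi-channel data.
    """
    volumes = []
    for data, pattern in zip(dataset.frames, dataset.patterns):
        m = matrix or pattern.matrix
        if m is None:
            raise ValueError("matrix unknown: pass matrix= explicitly")
        chans = []
        for c in range(data.shape[0]):
            if pattern.cartesian:
                img = inverse_cartesian(samples_to_grid(data[c], pattern.coords, m))
            else:
                warnings.warn("non-Cartesian data: best-effort adjoint reconstruction")
                img = adjoint_nudft(data[c], pattern.coords, m)
            chans.append(img)
        volumes.append(chans[0] if len(chans) == 1 else rss_combine(np.stack(chans)))
    return volumes


def rss_combine(channel_images: np.ndarray) -> np.ndarray:
    """Root-sum-of-squares magnitude over the leading channel axis."""
    return np.sqrt(np.sum(np.abs(channel_images) ** 2, axis=0))


def measure_snr(image: np.ndarray, tissue_mask: np.ndarray, noise_region: np.ndarray) -> float:
    """Mean tissue magnitude divided by the corrected noise SD.

    For complex images the noise SD is read from the real channel of the
    signal-free region; for magnitude images the background follows a
    Rayleigh distribution and its SD is divided by sqrt(2 - pi/2).
    Returns inf for a noiseless image.
    """
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    noise_region = np.asarray(noise_region, dtype=bool)
    if not tissue_mask.any() or not noise_region.any():
        raise ValueError("tissue mask and noise region must be nonempty")
    if (tissue_mask & noise_region).any():
        raise ValueError("tissue mask and noise region must be disjoint")
    mean_tissue = float(np.abs(image)[tissue_mask].mean())
    if np.iscomplexobj(image):
        sigma = float(np.std(image.real[noise_region]))
    else:
        sigma = float(np.std(image[noise_region])) / RAYLEIGH_SD_FACTOR
    if sigma == 0:
        return float("inf")
    return mean_tissue / sigma
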