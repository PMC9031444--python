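"""Fourier evaluation of image volumes at k-space sample locations.

Conventions: k-space coordinates are in cycles/FOV with DC at the centre of
the grid; Cartesian integer indices span [-N/2, N/2). The spatial origin
sits at voxel N//2 along each axis, so the DC sample equals the plain sum
of image voxels and a centred inverse FFT returns the image.

Cartesian samples are read off a single centred FFT of the volume.
Off-grid samples are evaluated by an exact non-uniform discrete Fourier
transform, computed with a separable axis factorisation and chunking over
samples; it is exact (no gridding approximation), which is affordable at
the desk-scale volumes this package targets.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "cartesian_kspace",
    "nudft",
    "kspace_at",
    "inverse_cartesian",
    "adjoint_nudft",
    "samples_to_grid",
]


def _check_nyquist(coords: np.ndarray, matrix) -> None:
    half = np.asarray(matrix) / 2.0
    if np.any(coords < -half[None, :]) or np.any(coords >= half[None, :]):
        raise ValueError("k-space coords outside the Nyquist box [-N/2, N/2)")


def cartesian_kspace(image: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """FFT samples of ``image`` at integer coords (cycles/FOV)."""
    coords = np.asarray(coords)
    if not np.allclose(coords, np.round(coords)):
        raise ValueError("cartesian_kspace requires integer coords")
    _check_nyquist(coords, image.shape)
    k = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(image)))
    idx = (np.round(coords) + np.array(image.shape) // 2).astype(int)
    return k[idx[:, 0], idx[:, 1], idx[:, 2]]


def nudft(image: np.ndarray, coords: np.ndarray, chunk: int = 512) -> np.ndarray:
    """Exact type-2 non-uniform DFT of ``image`` at arbitrary coords.

    F(k) = sum_n image[n] exp(-2i pi sum_d k_d (n_d - N_d//2) / N_d)
    """
    coords = np.asarray(coords, dtype=float)
    _check_nyquist(coords, image.shape)
    shape = image.shape
    pos = [np.arange(n) - n // 2 for n in shape]
    out = np.empty(coords.shape[0], dtype=complex)
    img = image.astype(complex)
    for start in range(0, coords.shape[0], chunk):
        c = coords[start : start + chunk]
        ex = np.exp(-2j * np.pi * np.outer(c[:, 0], pos[0]) / shape[0])
        ey = np.exp(-2j * np.pi * np.outer(c[:, 1], pos[1]) / shape[1])
        ez = np.exp(-2j * np.pi * np.outer(c[:, 2], pos[2]) / shape[2])
        t = np.einsum("mx,xyz->myz", ex, img, optimize=True)
        t = np.einsum("my,myz->mz", ey, t, optimize=True)
        out[start : start + chunk] = np.einsum("mz,mz->m", ez, t)
    return out


def kspace_at(image: np.ndarray, coords: np.ndarray, cartesian: bool) -> np.ndarray:
    """Dispatch: centred FFT lookup on-grid, exact non-uniform DFT off-grid."""
    if cartesian:
        return cartesian_kspace(image, coords)
    return nudft(image, coords)


def samples_to_grid(samples: np.ndarray, coords: np.ndarray, matrix) -> np.ndarray:
    """Scatter Cartesian samples into a centred k-space grid.

    Missing locations stay zero; duplicate locations are averaged.
    """
    coords = np.asarray(coords)
    _check_nyquist(coords, matrix)
    matrix = tuple(int(m) for m in matrix)
    grid = np.zeros(matrix, dtype=complex)
    count = np.zeros(matrix, dtype=np.int64)
    idx = tuple(
        (np.round(coords[:, d]) + matrix[d] // 2).astype(int) for d in range(3)
    )
    np.add.at(grid, idx, samples)
    np.add.at(count, idx, 1)
    if count.max() > 1:
        grid = np.where(count > 1, grid / np.maximum(count, 1), grid)
    if (count == 0).any():
        warnings.warn("k-space not fully sampled; missing locations zero-filled")
    return grid


def inverse_cartesian(kgrid: np.ndarray) -> np.ndarray:
    """Centred inverse FFT matching :func:`cartesian_kspace`."""
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(kgrid)))


def adjoint_nudft(samples: np.ndarray, coords: np.ndarray, matrix, chunk: int = 512) -> np.ndarray:
    """Adjoint non-uniform DFT (best-effort gridding-free reconstruction)."""
    coords = np.asarray(coords, dtype=float)
    _check_nyquist(coords, matrix)
    matrix = tuple(int(m) for m in matrix)
    pos = [np.arange(n) - n // 2 for n in matrix]
    out = np.zeros(matrix, dtype=complex)
    for start in range(0, coords.shape[0], chunk):
        c = coords[start : start + chunk]
        s = samples[start : start + chunk]
        ex = np.exp(2j * np.pi * np.outer(c[:, 0], pos[0]) / matrix[0])
        ey = np.exp(2j * np.pi * np.outer(c[:, 1], pos[1]) / matrix[1])
        ez = np.exp(2j * np.pi * np.outer(c[:, 2], pos[2]) / matrix[2])
        t = np.einsum("m,mx->mx", s, ex)
        t = np.einsum("mx,my->mxy", t, ey, optimize=True)
        out += np.einsum("mxy,mz->xyz", t, ez, optimize=True)
    return out / float(np.prod(matrix))
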