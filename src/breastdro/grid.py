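"""Voxel geometry shared by every module.

Axis order is fixed as (x, y, z) with 0-based voxel indices:
x = left/right (medial–lateral), y = posterior→anterior, z = inferior→superior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid"]


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3-D voxel lattice defined by matrix size and field of view.

    Parameters
    ----------
    matrix_size : tuple of int
        Number of voxels along (x, y, z). All entries must be positive.
    fov_mm : tuple of float
        Field of view in millimetres along (x, y, z).
    """

    matrix_size: tuple[int, int, int]
    fov_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.matrix_size) != 3 or len(self.fov_mm) != 3:
            raise ValueError("matrix_size and fov_mm must have 3 entries")
        if any(int(n) != n or n <= 0 for n in self.matrix_size):
            raise ValueError(f"matrix_size must be positive integers, got {self.matrix_size}")
        if any(f <= 0 for f in self.fov_mm):
            raise ValueError(f"fov_mm must be positive, got {self.fov_mm}")
        object.__setattr__(self, "matrix_size", tuple(int(n) for n in self.matrix_size))
        object.__setattr__(self, "fov_mm", tuple(float(f) for f in self.fov_mm))

    @property
    def voxel_mm(self) -> tuple[float, float, float]:
        """Voxel edge lengths in mm, fov / matrix."""
        return tuple(f / n for f, n in zip(self.fov_mm, self.matrix_size))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.matrix_size

    def zeros(self, dtype=np.float64) -> np.ndarray:
        return np.zeros(self.matrix_size, dtype=dtype)

    def coordinates_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinates in mm, origin at the grid centre.

        Returns a broadcastable (x, y, z) tuple following the FFT convention
        that voxel ``N//2`` sits at 0.
        """
        axes = []
        for n, d in zip(self.matrix_size, self.voxel_mm):
            axes.append((np.arange(n) - n // 2) * d)
        x, y, z = np.meshgrid(*axes, indexing="ij", sparse=True)
        return x, y, z

    def check_volume(self, vol: np.ndarray, name: str = "volume") -> np.ndarray:
        vol = np.asarray(vol)
        if vol.shape != self.matrix_size:
            raise ValueError(
                f"{name} shape {vol.shape} does not match grid matrix_size {self.matrix_size}"
            )
        return vol
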