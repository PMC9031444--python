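"""Procedural anthropomorphic breast phantom.

Generates bilateral, semi-ellipsoidal breast volumes with a skin shell, a
posterior chest-wall muscle slab, and a heterogeneous fibroglandular region
produced by thresholding a smoothed Gaussian random field, with continuous
partial-volume transitions between fat and fibroglandular tissue. The
output is a standard :class:`~breastdro.anatomy.AnatomyModel`, so every
downstream module can be exercised without any external image data.

Convention: in generated models the class base images are uniform amplitude
maps and the subtype masks carry the voxel content fractions, so that
``base_image x mask`` is the tissue signal and ``fat + water`` content never
exceeds 1 in any voxel.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import yaml
from scipy import ndimage

from .anatomy import (
    AnatomyModel,
    TissueClass,
    TissueSubtype,
    assign_water_subtypes,
    default_t1_table,
    load_anatomy,
)
from .grid import VoxelGrid
from .spectral import default_fat_spectrum, water_spectrum

__all__ = ["PhantomSpec", "generate_breast_phantom", "write_phantom", "DEFAULT_TEST_GRID"]

#: Desk-scale default grid: full simulations complete in seconds.
DEFAULT_TEST_GRID = VoxelGrid(matrix_size=(64, 64, 32), fov_mm=(160.0, 160.0, 64.0))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the procedural breast phantom.

    fibroglandular_fraction_target : fraction of the breast volume occupied
        by fibroglandular tissue (typical breasts span roughly 0.05-0.5).
    skin_thickness_mm : thickness of the skin shell (~2 mm in vivo).
    smoothness_mm : correlation length of the fibroglandular texture.
    """

    grid: VoxelGrid = DEFAULT_TEST_GRID
    fibroglandular_fraction_target: float = 0.2
    skin_thickness_mm: float = 2.5
    seed: int = 0
    smoothness_mm: float = 8.0

    def __post_init__(self) -> None:
        if not (0.0 < self.fibroglandular_fraction_target < 1.0):
            raise ValueError("fibroglandular_fraction_target must be in (0, 1)")
        if self.skin_thickness_mm <= 0 or self.smoothness_mm <= 0:
            raise ValueError("thickness and smoothness must be positive")


def generate_breast_phantom(spec: PhantomSpec) -> AnatomyModel:
    """Generate a bilateral breast phantom; bit-identical for a given seed."""
    grid = spec.grid
    nx, ny, nz = grid.matrix_size
    x, y, z = grid.coordinates_mm()
    fx, fy, fz = grid.fov_mm

    # Posterior chest wall occupies the back ~15% of the AP field of view.
    y_chest = -fy / 2 + 0.15 * fy
    muscle = np.broadcast_to(y < y_chest, grid.matrix_size).copy()

    # Two semi-ellipsoids protruding anteriorly from the chest wall.
    rx = 0.23 * fx
    ry = 0.78 * (fy / 2 - y_chest)
    rz = 0.42 * fz
    if min(rx, ry, rz) < 3 * max(grid.voxel_mm):
        raise ValueError("grid too small to contain the breast geometry")
    if spec.skin_thickness_mm >= min(rx, ry, rz):
        raise ValueError("skin thickness exceeds the breast radius")
    breast = np.zeros(grid.matrix_size, dtype=bool)
    for cx in (-0.25 * fx, 0.25 * fx):
        e = ((x - cx) / rx) ** 2 + ((y - y_chest) / ry) ** 2 + (z / rz) ** 2
        breast |= (e <= 1.0) & (y >= y_chest)

    # Skin: surface shell obtained by eroding the breast mask.
    n_erode = max(1, int(round(spec.skin_thickness_mm / min(grid.voxel_mm))))
    interior = ndimage.binary_erosion(breast, iterations=n_erode)
    skin = breast & ~interior

    # Fibroglandular texture: smoothed Gaussian random field, thresholded at
    # the quantile that realises the target fraction of the breast volume,
    # softened into a continuous partial-volume fraction.
    rng = np.random.default_rng(spec.seed)
    field = rng.standard_normal(grid.matrix_size)
    sigma_vox = [spec.smoothness_mm / d for d in grid.voxel_mm]
    field = ndimage.gaussian_filter(field, sigma=sigma_vox)
    field /= field.std()
    # Bias toward the central/posterior breast where fibroglandular tissue sits.
    for cx in (-0.25 * fx, 0.25 * fx):
        r2 = ((x - cx) / (0.6 * rx)) ** 2 + ((y - y_chest) / (0.7 * ry)) ** 2 + (
            z / (0.6 * rz)
        ) ** 2
        field = np.where(
            ((x - cx) / rx) ** 2 + ((y - y_chest) / ry) ** 2 + (z / rz) ** 2 <= 1.0,
            field + np.maximum(0.0, 1.5 * (1.0 - np.sqrt(r2))),
            field,
        )

    n_target = spec.fibroglandular_fraction_target * breast.sum()
    vals = field[interior]
    if n_target > vals.size:
        raise ValueError("target fibroglandular fraction exceeds the breast interior")
    thr = np.quantile(vals, 1.0 - n_target / vals.size)
    soft = 0.15  # width of the sigmoid transition, in field SD units
    fib = np.clip((field - thr) / (2 * soft) + 0.5, 0.0, 1.0)
    fib = np.where(interior, fib, 0.0)

    fat_frac = np.where(interior, 1.0 - fib, 0.0)
    t1 = default_t1_table()

    fat_class = TissueClass(
        name="fat",
        base_image=np.where(fat_frac > 0, 1.0, 0.0),
        spectral_model=default_fat_spectrum(),
        subtypes=[TissueSubtype("fat", fat_frac, t1_ms=t1["fat"])],
    )
    water_content = fib + skin + muscle
    water_class = TissueClass(
        name="water",
        base_image=np.where(water_content > 0, 1.0, 0.0),
        spectral_model=water_spectrum(),
        subtypes=[
            TissueSubtype("fibroglandular", fib, t1_ms=t1["fibroglandular"]),
            TissueSubtype("skin", skin.astype(float), t1_ms=t1["skin"]),
            TissueSubtype("muscle", muscle.astype(float), t1_ms=t1["muscle"]),
        ],
    )
    return AnatomyModel(grid=grid, classes=[fat_class, water_class]).validate()


def write_phantom(model: AnatomyModel, directory) -> dict:
    """Write an anatomy model as NIfTI volumes plus a YAML manifest.

    Emits separated fat/water volumes (``base_image x mask`` per class) and
    one mask volume per water subtype, normalised to the water content so a
    write -> load -> write cycle is idempotent and voxel values round-trip
    within float32 precision. Returns the manifest dict.
    """
    import nibabel as nib

    os.makedirs(directory, exist_ok=True)
    grid = model.grid
    affine = np.diag(list(grid.voxel_mm) + [1.0])

    def _save(name: str, vol: np.ndarray) -> str:
        img = nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine)
        path = os.path.join(directory, f"{name}.nii.gz")
        nib.save(img, path)
        return f"{name}.nii.gz"

    fat = model.tissue_class("fat")
    water = model.tissue_class("water")
    fat_img = sum(fat.base_image * st.mask for st in fat.subtypes)
    water_img = sum(water.base_image * st.mask for st in water.subtypes)

    manifest = {
        "grid": {"matrix_size": list(grid.matrix_size), "fov_mm": list(grid.fov_mm)},
        "fat_volume": _save("fat", fat_img),
        "water_volume": _save("water", water_img),
        "water_subtypes": {},
        "t1_ms": {"fat": fat.subtypes[0].t1_ms if fat.subtypes else None},
    }
    with np.errstate(invalid="ignore", divide="ignore"):
        for st in water.subtypes:
            signal = water.base_image * st.mask
            norm = np.where(water_img > 0, signal / np.where(water_img > 0, water_img, 1.0), 0.0)
            manifest["water_subtypes"][st.name] = _save(f"mask_{st.name}", norm)
            manifest["t1_ms"][st.name] = st.t1_ms
    path = os.path.join(directory, "manifest.yaml")
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


def load_phantom(directory) -> AnatomyModel:
    """Load a phantom written by :func:`write_phantom` back into a model."""
    with open(os.path.join(directory, "manifest.yaml")) as fh:
        manifest = yaml.safe_load(fh)
    import nibabel as nib

    grid = VoxelGrid(
        matrix_size=tuple(manifest["grid"]["matrix_size"]),
        fov_mm=tuple(manifest["grid"]["fov_mm"]),
    )
    masks = {
        name: np.asarray(nib.load(os.path.join(directory, fname)).get_fdata())
        for name, fname in manifest["water_subtypes"].items()
    }
    t1 = {k: v for k, v in manifest["t1_ms"].items() if v is not None}
    ref = masks.get("fibroglandular")
    model = load_anatomy(
        os.path.join(directory, manifest["fat_volume"]),
        os.path.join(directory, manifest["water_volume"]),
        grid,
        t1_table=t1,
        water_reference_mask=(ref > 0.5) if ref is not None else None,
        scale_fat=False,  # writer already emits proton-density-consistent levels
    )
    return assign_water_subtypes(model, masks, t1_table=t1)
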