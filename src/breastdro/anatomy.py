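"""Tissue-class anatomy model.

The anatomy is organised as chemical-species *tissue classes* (fat, water),
each with a base image (equilibrium signal amplitude per voxel, arbitrary
units), a spectral model, and a list of *tissue subtypes*. Each subtype is a
continuous partial-volume mask in [0, 1] on the shared voxel grid together
with relaxation times (T1, optionally T2*) and, optionally, kinetic
parameters driving its contrast enhancement. Subtype masks partition their
class: their voxelwise sum never exceeds 1.

Background parenchymal enhancement (BPE) is modelled by reassigning a chosen
fraction of fibroglandular voxels to new concentric BPE subtypes, with
selection weighted toward the upper-outer quadrants of each breast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml
from scipy import ndimage

from .grid import VoxelGrid
from .spectral import SpectralModel, default_fat_spectrum, water_spectrum

__all__ = [
    "TissueSubtype",
    "TissueClass",
    "AnatomyModel",
    "BpeSpec",
    "DEFAULT_T1_MS",
    "load_anatomy",
    "assign_water_subtypes",
    "assign_bpe",
    "default_t1_table",
]

_PARTITION_TOL = 1e-6

#: Default longitudinal relaxation times at 1.5 T (ms), literature values
#: for breast adipose, skin, chest-wall muscle and fibroglandular tissue.
DEFAULT_T1_MS = {
    "fat": 296.0,
    "skin": 887.0,
    "muscle": 1130.0,
    "fibroglandular": 1266.0,
}


def default_t1_table() -> dict[str, float]:
    """T1 defaults (ms) from the bundled tissue table, fallback to built-ins."""
    ref = resources.files("breastdro") / "data" / "tissue_t1.yaml"
    try:
        with resources.as_file(ref) as path, open(path) as fh:
            doc = yaml.safe_load(fh)
        return {k: float(v) for k, v in doc["t1_ms"].items()}
    except FileNotFoundError:  # pragma: no cover
        return dict(DEFAULT_T1_MS)


@dataclass
class TissueSubtype:
    """A named sub-region of a tissue class.

    ``mask`` is a continuous partial-volume mask in [0, 1]; binary masks are
    the special case with values in {0, 1}.
    """

    name: str
    mask: np.ndarray
    t1_ms: float
    t2_ms: float | None = None
    kinetic_params: object | None = None  # physiology.KineticParams

    def validate(self, grid: VoxelGrid) -> None:
        grid.check_volume(self.mask, f"subtype '{self.name}' mask")
        if self.mask.min() < 0 or self.mask.max() > 1 + _PARTITION_TOL:
            raise ValueError(f"subtype '{self.name}' mask values outside [0, 1]")
        if self.t1_ms <= 0:
            raise ValueError(f"subtype '{self.name}' t1_ms must be positive")


@dataclass
class TissueClass:
    """A chemical species: base image, spectral model, subtypes."""

    name: str
    base_image: np.ndarray
    spectral_model: SpectralModel
    subtypes: list[TissueSubtype] = field(default_factory=list)

    def validate(self, grid: VoxelGrid) -> None:
        grid.check_volume(self.base_image, f"class '{self.name}' base_image")
        if self.base_image.min() < 0:
            raise ValueError(f"class '{self.name}' base_image has negative values")
        for st in self.subtypes:
            st.validate(grid)
        if self.subtypes:
            total = self.subtype_mask_sum()
            if total.max() > 1 + _PARTITION_TOL:
                raise ValueError(
                    f"class '{self.name}' subtype masks sum to "
                    f"{total.max():.6f} > 1 somewhere"
                )

    def subtype_mask_sum(self) -> np.ndarray:
        if not self.subtypes:
            return np.zeros_like(self.base_image)
        return np.sum([st.mask for st in self.subtypes], axis=0)

    def subtype(self, name: str) -> TissueSubtype:
        for st in self.subtypes:
            if st.name == name:
                return st
        raise KeyError(f"class '{self.name}' has no subtype '{name}'")


@dataclass
class AnatomyModel:
    """Voxel grid plus the tissue classes defined on it."""

    grid: VoxelGrid
    classes: list[TissueClass]

    def validate(self) -> "AnatomyModel":
        for cls in self.classes:
            cls.validate(self.grid)
        return self

    def tissue_class(self, name: str) -> TissueClass:
        for cls in self.classes:
            if cls.name == name:
                return cls
        raise KeyError(f"anatomy has no tissue class '{name}'")

    def breast_mask(self) -> np.ndarray:
        """Support of any tissue: voxels with nonzero base image in any class."""
        mask = np.zeros(self.grid.matrix_size, dtype=bool)
        for cls in self.classes:
            mask |= cls.base_image > 0
        return mask

    def iter_subtypes(self):
        """Yield (tissue_class, subtype) pairs; classes with no subtypes
        yield a synthetic whole-class subtype so the simulator can treat
        every class uniformly."""
        for cls in self.classes:
            if cls.subtypes:
                for st in cls.subtypes:
                    yield cls, st
            else:
                yield cls, TissueSubtype(
                    name=cls.name,
                    mask=(cls.base_image > 0).astype(float),
                    t1_ms=DEFAULT_T1_MS.get(cls.name, 1000.0),
                )


@dataclass(frozen=True)
class BpeSpec:
    """Background parenchymal enhancement assignment.

    fraction : target fraction of fibroglandular voxels reassigned to BPE.
    n_levels : number of concentric BPE sub-regions (4 for the clinical
        minimal / mild / moderate / marked grades).
    quadrant_weight : selection weight of upper-outer-quadrant voxels
        relative to the rest (>= 1); BPE is seen preferentially there.
    """

    fraction: float
    n_levels: int = 4
    quadrant_weight: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError(f"fraction {self.fraction} outside [0, 1]")
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.quadrant_weight < 1:
            raise ValueError("quadrant_weight must be >= 1")


#: BIRADS-style BPE category presets (fraction of fibroglandular tissue).
BPE_CATEGORY_FRACTIONS = {
    "minimal": 0.10,
    "mild": 0.25,
    "moderate": 0.50,
    "marked": 0.75,
}


def load_anatomy(
    fat_volume,
    water_volume,
    grid: VoxelGrid,
    t1_table: dict[str, float] | None = None,
    fat_spectrum: SpectralModel | None = None,
    water_reference_mask: np.ndarray | None = None,
    scale_fat: bool = True,
) -> AnatomyModel:
    """Build an AnatomyModel from separated fat and water volumes.

    ``fat_volume`` / ``water_volume`` may be NIfTI file paths or arrays.
    The fat base image is rescaled so its mean signal over the fat support
    matches the water mean over ``water_reference_mask`` (the fibroglandular
    mask when known, else the water support), emulating proton-density-like
    weighting with approximately equal fat and fibroglandular signal levels.
    """
    fat = _as_volume(fat_volume)
    water = _as_volume(water_volume)
    if fat.shape != water.shape:
        raise ValueError(f"fat shape {fat.shape} != water shape {water.shape}")
    grid.check_volume(fat, "fat volume")
    if fat.min() < 0 or water.min() < 0:
        raise ValueError("volumes must be nonnegative")

    t1 = dict(default_t1_table())
    if t1_table:
        t1.update(t1_table)

    fat = fat.astype(float).copy()
    water = water.astype(float).copy()
    fat_support = fat > 0
    if water_reference_mask is not None:
        ref = np.asarray(water_reference_mask) > 0
    else:
        ref = water > 0
    if scale_fat and fat_support.any() and ref.any() and water[ref].mean() > 0 and fat[fat_support].mean() > 0:
        fat *= water[ref].mean() / fat[fat_support].mean()

    fat_class = TissueClass(
        name="fat",
        base_image=fat,
        spectral_model=fat_spectrum or default_fat_spectrum(),
        subtypes=[TissueSubtype("fat", fat_support.astype(float), t1_ms=t1["fat"])],
    )
    water_class = TissueClass(name="water", base_image=water, spectral_model=water_spectrum())
    return AnatomyModel(grid=grid, classes=[fat_class, water_class]).validate()


def _as_volume(vol) -> np.ndarray:
    if isinstance(vol, np.ndarray):
        return vol
    import nibabel as nib

    return np.asarray(nib.load(str(vol)).get_fdata())


def assign_water_subtypes(
    model: AnatomyModel,
    subtype_masks: dict[str, np.ndarray],
    t1_table: dict[str, float] | None = None,
) -> AnatomyModel:
    """Attach named subtypes (fibroglandular, skin, muscle, ...) to water.

    Masks may be binary or continuous; their voxelwise sum must not exceed 1.
    """
    t1 = dict(default_t1_table())
    if t1_table:
        t1.update(t1_table)
    water = model.tissue_class("water")
    names = list(subtype_masks)
    if len(set(names)) != len(names):
        raise ValueError("subtype labels must be unique")
    subtypes = []
    for name, mask in subtype_masks.items():
        mask = np.asarray(mask, dtype=float)
        if name not in t1:
            raise KeyError(f"no T1 value for subtype '{name}' in t1_table")
        subtypes.append(TissueSubtype(name=name, mask=mask, t1_ms=t1[name]))
    water.subtypes = subtypes
    total = water.subtype_mask_sum()
    if total.max() > 1 + _PARTITION_TOL:
        raise ValueError(f"subtype masks overlap: sum reaches {total.max():.4f} > 1")
    return model.validate()


def upper_outer_quadrant_mask(breast_mask: np.ndarray) -> np.ndarray:
    """Upper-outer-quadrant voxels, determined per breast side.

    The breast mask is split at the midline into left/right sides; within
    each side's bounding box, 'outer' is the lateral half (away from the
    midline) and 'upper' the superior half, split at the side's centroid.
    """
    breast_mask = np.asarray(breast_mask, dtype=bool)
    out = np.zeros_like(breast_mask)
    if not breast_mask.any():
        return out
    xs = np.nonzero(breast_mask.any(axis=(1, 2)))[0]
    x_mid = 0.5 * (xs[0] + xs[-1])
    for side in ("left", "right"):
        side_mask = np.zeros_like(breast_mask)
        if side == "left":
            side_mask[: int(np.ceil(x_mid)) + 1] = True
        else:
            side_mask[int(np.ceil(x_mid)) :] = True
        side_mask &= breast_mask
        if not side_mask.any():
            continue
        cx, _, cz = ndimage.center_of_mass(side_mask)
        ix, iy, iz = np.nonzero(side_mask)
        lateral = ix <= cx if side == "left" else ix >= cx
        upper = iz >= cz
        sel = lateral & upper
        out[ix[sel], iy[sel], iz[sel]] = True
    return out


def assign_bpe(model: AnatomyModel, spec: BpeSpec) -> AnatomyModel:
    """Reassign a fraction of fibroglandular voxels to concentric BPE subtypes.

    Voxels are drawn without replacement with upper-outer-quadrant voxels
    weighted ``quadrant_weight``-fold; the selected set is split into
    ``n_levels`` concentric shells by erosion depth, the innermost shell
    being the highest enhancement level. Deterministic given ``spec.seed``.
    """
    water = model.tissue_class("water")
    fib = water.subtype("fibroglandular")
    support = np.nonzero(fib.mask > 0)
    n_fib = support[0].size
    if n_fib == 0:
        if spec.fraction > 0:
            raise ValueError("BPE requested but the fibroglandular mask is empty")
        return model
    n_sel = int(round(spec.fraction * n_fib))
    if n_sel == 0:
        return model

    uoq = upper_outer_quadrant_mask(model.breast_mask())
    weights = np.where(uoq[support], spec.quadrant_weight, 1.0)
    rng = np.random.default_rng(spec.seed)
    idx = rng.choice(n_fib, size=n_sel, replace=False, p=weights / weights.sum())

    selected = np.zeros(model.grid.matrix_size, dtype=bool)
    selected[support[0][idx], support[1][idx], support[2][idx]] = True

    # Concentric levels: erosion depth of the selected mask, innermost last.
    depth = ndimage.distance_transform_cdt(selected, metric="chessboard")
    new_subtypes = [st for st in water.subtypes]
    fib_mask = fib.mask.copy()
    for level in range(1, spec.n_levels + 1):
        if level < spec.n_levels:
            shell = depth == level
        else:
            shell = depth >= level
        mask = np.where(shell, fib_mask, 0.0)
        new_subtypes.append(
            TissueSubtype(name=f"bpe_level{level}", mask=mask, t1_ms=fib.t1_ms)
        )
    fib_new = np.where(selected, 0.0, fib_mask)
    for i, st in enumerate(new_subtypes):
        if st.name == "fibroglandular":
            new_subtypes[i] = replace(st, mask=fib_new)
    water.subtypes = new_subtypes
    return model.validate()
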