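"""Simulated breast lesions: morphology, enhancement subtypes, insertion.

Lesion shapes follow the four BIRADS mass-morphology classes (round,
lobulated, irregular, spiculated). Round/lobulated/irregular masks are
unions of randomly placed overlapping spheres; spiculated lesions add
tapering radial spicules to a compact core. Sphere geometry is generated in
a normalised space and rescaled analytically so the longest extent of the
union equals the requested diameter, then digitised onto the voxel grid
with a continuous partial-volume boundary.

Enhancement heterogeneity is expressed through lesion subtypes: a rim/core
split by morphological erosion, or a pseudo-random voxel partition, each
subtype carrying its own kinetic parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .anatomy import AnatomyModel, TissueSubtype
from .grid import VoxelGrid
from .kinetics import KineticParams

__all__ = [
    "LesionSpec",
    "Lesion",
    "MORPHOLOGIES",
    "generate_lesion_mask",
    "assign_rim_enhancement",
    "assign_heterogeneous_enhancement",
    "insert_lesion",
]

MORPHOLOGIES = ("round", "lobulated", "irregular", "spiculated")

# (n_spheres, relative sphere radius range, relative centre jitter) defaults
# per morphology; the construction is only pinned down as "randomly placed
# overlapping spheres", so these are documented, configurable choices.
_MORPH_DEFAULTS = {
    "round": (3, (0.92, 1.0), 0.06),
    "lobulated": (4, (0.52, 0.70), 0.42),
    "irregular": (15, (0.22, 0.40), 0.70),
    "spiculated": (3, (0.85, 1.0), 0.08),
}


@dataclass(frozen=True)
class LesionSpec:
    """User-facing lesion description.

    diameter_mm is the longest extent of the final mask; subtype_params maps
    subtype labels (e.g. ``core`` or ``rim``/``core``) to kinetic parameters.
    """

    morphology: str
    diameter_mm: float
    center_voxel: tuple[int, int, int]
    seed: int = 0
    n_spheres: int | None = None
    n_spicules: int = 8
    spicule_length_mm: float | None = None
    rim_thickness_voxels: int | None = None
    subtype_params: dict[str, KineticParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.morphology not in MORPHOLOGIES:
            raise ValueError(f"morphology must be one of {MORPHOLOGIES}")
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive")


@dataclass
class Lesion:
    """Continuous lesion mask plus its subtype partition."""

    mask: np.ndarray
    subtype_masks: dict[str, np.ndarray]
    grayscale_values: np.ndarray | None = None
    spec: LesionSpec | None = None

    @property
    def binary_mask(self) -> np.ndarray:
        return self.mask >= 0.5


def _sphere_geometry(spec: LesionSpec, rng: np.random.Generator):
    """Sphere centres/radii (unit scale) and spicule segments for a spec."""
    n_default, r_range, jitter = _MORPH_DEFAULTS[spec.morphology]
    n = spec.n_spheres if spec.n_spheres is not None else n_default
    if spec.morphology == "round" and spec.n_spheres == 1:
        centers = np.zeros((1, 3))
        radii = np.array([1.0])
    else:
        centers = rng.uniform(-jitter, jitter, size=(n, 3))
        radii = rng.uniform(*r_range, size=n)
    spicules = []
    if spec.morphology == "spiculated":
        core_r = radii.max()
        length = spec.spicule_length_mm  # resolved to unit scale by caller
        rel_len = 0.8 if length is None else None
        for _ in range(spec.n_spicules):
            d = rng.standard_normal(3)
            d /= np.linalg.norm(d)
            i = int(rng.integers(len(centers)))
            base = centers[i] + d * radii[i] * 0.8
            L = rel_len * core_r if rel_len is not None else length
            spicules.append((base, base + d * L, 0.25 * core_r))
    return centers, radii, spicules


def _extent(centers, radii, spicules) -> float:
    """Longest extent of a union of spheres and spicule segments."""
    pts = [(c, r) for c, r in zip(centers, radii)]
    for base, tip, _ in spicules:
        pts.append((tip, 0.0))
    best = 0.0
    for i, (ci, ri) in enumerate(pts):
        for cj, rj in pts[i:]:
            best = max(best, float(np.linalg.norm(ci - cj)) + ri + rj)
    return best


def _digitize(centers, radii, spicules, X, Y, Z, pv_width, min_spicule_r):
    pv = np.zeros(X.shape)
    for c, r in zip(centers, radii):
        d = np.sqrt((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2)
        pv = np.maximum(pv, np.clip((r - d) / pv_width + 0.5, 0.0, 1.0))
    for base, tip, r0 in spicules:
        r0 = max(r0, min_spicule_r)  # keep spicules resolvable on the grid
        seg = tip - base
        L2 = float(seg @ seg)
        px, py, pz = X - base[0], Y - base[1], Z - base[2]
        t = np.clip((px * seg[0] + py * seg[1] + pz * seg[2]) / L2, 0.0, 1.0)
        d = np.sqrt((px - t * seg[0]) ** 2 + (py - t * seg[1]) ** 2 + (pz - t * seg[2]) ** 2)
        r_local = r0 * (1.0 - 0.5 * t)  # taper toward the tip
        pv = np.maximum(pv, np.clip((r_local - d) / pv_width + 0.5, 0.0, 1.0))
    return pv


def _support_extent_mm(support: np.ndarray, vox: np.ndarray) -> float:
    """Longest extent of a binary support: max pairwise voxel-centre distance."""
    pts = np.argwhere(support) * vox
    if len(pts) < 2:
        return float(vox.min())
    if len(pts) > 400:  # pairwise over hull vertices only
        from scipy.spatial import ConvexHull, QhullError

        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass
    from scipy.spatial.distance import pdist

    return float(pdist(pts).max())


def generate_lesion_mask(spec: LesionSpec, grid: VoxelGrid) -> Lesion:
    """Generate a lesion mask of the requested morphology and diameter.

    Deterministic given ``spec.seed``; the longest extent of the binary
    support matches ``diameter_mm`` to within one voxel. The geometry is
    scaled analytically to the requested extent, then corrected against the
    measured extent of the digitised support (digitisation shrinks thin
    features such as spicule tips). Raises if the lesion would exceed the
    grid bounds.
    """
    rng = np.random.default_rng(spec.seed)
    centers0, radii0, spicules0 = _sphere_geometry(spec, rng)
    ext = _extent(centers0, radii0, spicules0)
    scale = spec.diameter_mm / ext

    vox = np.array(grid.voxel_mm)
    center_mm = np.array(spec.center_voxel, dtype=float) * vox  # grid-corner origin
    half = spec.diameter_mm / 2 + 3 * vox.max()
    lo = np.maximum(np.floor((center_mm - half) / vox).astype(int), 0)
    hi = np.minimum(np.ceil((center_mm + half) / vox).astype(int) + 1, grid.matrix_size)
    if np.any(lo >= hi):
        raise ValueError("lesion centre lies outside the grid")
    ax = [np.arange(lo[k], hi[k]) * vox[k] - center_mm[k] for k in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pv_width = float(np.mean(vox))
    min_spicule_r = 0.55 * float(vox.max())

    tol = float(vox.max())
    pv = None
    for _ in range(4):
        centers = centers0 * scale
        radii = radii0 * scale
        spicules = [(b * scale, t * scale, r * scale) for b, t, r in spicules0]
        pv = _digitize(centers, radii, spicules, X, Y, Z, pv_width, min_spicule_r)
        support_box = pv >= 0.5
        if not support_box.any():
            raise ValueError("lesion mask is empty (diameter below voxel size?)")
        measured = _support_extent_mm(support_box, vox)
        if abs(measured - spec.diameter_mm) <= tol:
            break
        scale *= spec.diameter_mm / measured

    mask = grid.zeros()
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = pv
    support = mask >= 0.5
    for k, n in enumerate(grid.matrix_size):
        proj = support.any(axis=tuple(j for j in range(3) if j != k))
        if proj[0] or proj[-1]:
            raise ValueError("lesion exceeds the grid bounds")
    return Lesion(mask=mask, subtype_masks={"core": mask.copy()}, spec=spec)


_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connected


def assign_rim_enhancement(lesion: Lesion, rim_thickness_voxels: int) -> Lesion:
    """Split the lesion into rim and core subtypes.

    The core is the binary support eroded ``rim_thickness_voxels`` times
    (6-connected); the rim is the remainder. Raises when the erosion removes
    the core entirely (rim thickness too large for the lesion).
    """
    if rim_thickness_voxels < 1:
        raise ValueError("rim thickness must be >= 1 voxel")
    support = lesion.binary_mask
    if not support.any():
        raise ValueError("lesion mask is empty")
    core = ndimage.binary_erosion(support, structure=_STRUCT, iterations=rim_thickness_voxels)
    if not core.any():
        raise ValueError(
            "erosion removed the whole lesion: choose a smaller rim thickness"
        )
    rim = support & ~core
    lesion.subtype_masks = {
        "rim": np.where(rim, lesion.mask, 0.0) + np.where(~support, lesion.mask, 0.0),
        "core": np.where(core, lesion.mask, 0.0),
    }
    return lesion


def assign_heterogeneous_enhancement(
    lesion: Lesion, labels: list[str], fractions: list[float], seed: int = 0
) -> Lesion:
    """Pseudo-randomly partition lesion voxels among labelled subtypes."""
    if len(labels) != len(fractions):
        raise ValueError("labels and fractions must have equal length")
    fr = np.asarray(fractions, dtype=float)
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions sum to {fr.sum()}, expected 1")
    support = np.nonzero(lesion.mask > 0)
    n = support[0].size
    rng = np.random.default_rng(seed)
    assignment = rng.permutation(n)
    bounds = np.round(np.cumsum(fr) * n).astype(int)
    lesion.subtype_masks = {}
    start = 0
    for label, stop in zip(labels, bounds):
        sel = assignment[start:stop]
        m = np.zeros_like(lesion.mask)
        m[support[0][sel], support[1][sel], support[2][sel]] = lesion.mask[
            support[0][sel], support[1][sel], support[2][sel]
        ]
        lesion.subtype_masks[label] = m
        start = stop
    return lesion


def insert_lesion(model: AnatomyModel, lesion: Lesion, seed: int = 0) -> AnatomyModel:
    """Insert a lesion into the anatomy as new water subtypes.

    Lesion voxels in the water base image receive grayscale values drawn to
    match the mean and SD of the fibroglandular tissue; overlapping fat is
    displaced (fat content zeroed where the lesion binary mask is set), so
    lesions may extend into fat. Each lesion subtype becomes a water-class
    subtype carrying its kinetic parameters.
    """
    if not (lesion.mask > 0).any():
        return model
    water = model.tissue_class("water")
    fib = water.subtype("fibroglandular")
    fib_vox = fib.mask > 0.5
    if not fib_vox.any():
        raise ValueError("no fibroglandular voxels to estimate lesion grayscale from")
    values = water.base_image[fib_vox]
    mean, sd = float(values.mean()), float(values.std())

    rng = np.random.default_rng(seed)
    binary = lesion.binary_mask
    drawn = np.maximum(rng.normal(mean, sd, size=int(binary.sum())), 0.0)
    water.base_image = water.base_image.copy()
    water.base_image[binary] = drawn
    lesion.grayscale_values = drawn

    # Displace fat and carve the lesion out of existing water subtypes.
    fat = model.tissue_class("fat")
    fat.base_image = np.where(binary, 0.0, fat.base_image)
    for st in fat.subtypes:
        st.mask = np.where(binary, 0.0, st.mask)
    for st in water.subtypes:
        st.mask = st.mask * np.clip(1.0 - lesion.mask, 0.0, 1.0)

    params = lesion.spec.subtype_params if lesion.spec else {}
    for label, m in lesion.subtype_masks.items():
        water.subtypes.append(
            TissueSubtype(
                name=f"lesion_{label}",
                mask=m,
                t1_ms=fib.t1_ms,
                kinetic_params=params.get(label),
            )
        )
    return model.validate()
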