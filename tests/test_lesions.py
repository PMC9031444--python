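import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial.distance import pdist

from breastdro.grid import VoxelGrid
from breastdro.kinetics import KineticParams
from breastdro.lesions import (
    LesionSpec,
    assign_heterogeneous_enhancement,
    assign_rim_enhancement,
    generate_lesion_mask,
    insert_lesion,
)


def longest_extent_mm(support, vox):
    pts = np.argwhere(support) * np.asarray(vox)
    return pdist(pts).max() if len(pts) > 1 else 0.0


class TestMorphologies:
    # BIRADS morphology demo settings: diameters 10 / 12.5 / 12.5 / 15 mm.
    @pytest.mark.parametrize(
        "morph,diameter",
        [("round", 10.0), ("lobulated", 12.5), ("irregular", 12.5), ("spiculated", 15.0)],
    )
    @pytest.mark.parametrize("seed", [0, 3])
    def test_extent_within_one_voxel(self, grid, morph, diameter, seed):
        spec = LesionSpec(morph, diameter, (32, 32, 16), seed=seed)
        lesion = generate_lesion_mask(spec, grid)
        ext = longest_extent_mm(lesion.binary_mask, grid.voxel_mm)
        assert abs(ext - diameter) <= max(grid.voxel_mm)
        assert lesion.mask.min() >= 0 and lesion.mask.max() <= 1

    def test_single_sphere_is_exact_digital_ball(self, grid):
        spec = LesionSpec("round", 10.0, (32, 32, 16), seed=0, n_spheres=1)
        lesion = generate_lesion_mask(spec, grid)
        x, y, z = np.meshgrid(*[np.arange(n) for n in grid.matrix_size], indexing="ij")
        vox = grid.voxel_mm
        d = np.sqrt(
            ((x - 32) * vox[0]) ** 2 + ((y - 32) * vox[1]) ** 2 + ((z - 16) * vox[2]) ** 2
        )
        assert np.array_equal(lesion.binary_mask, d <= 5.0)

    def test_deterministic_given_seed(self, grid):
        spec = LesionSpec("irregular", 12.5, (32, 32, 16), seed=9)
        a = generate_lesion_mask(spec, grid)
        b = generate_lesion_mask(spec, grid)
        assert np.array_equal(a.mask, b.mask)

    def test_out_of_bounds_rejected(self, grid):
        with pytest.raises(ValueError, match="bounds|outside"):
            generate_lesion_mask(LesionSpec("round", 10.0, (1, 1, 1), seed=0), grid)
        with pytest.raises(ValueError):
            generate_lesion_mask(LesionSpec("round", 500.0, (32, 32, 16), seed=0), grid)

    def test_unknown_morphology_rejected(self):
        with pytest.raises(ValueError, match="morphology"):
            LesionSpec("oval", 10.0, (32, 32, 16))


class TestRimEnhancement:
    def test_matches_brute_force_erosion(self, grid):
        lesion = generate_lesion_mask(
            LesionSpec("round", 20.0, (32, 32, 16), seed=0, n_spheres=1), grid
        )
        support = lesion.binary_mask
        assign_rim_enhancement(lesion, 1)
        # brute-force oracle: voxel stays in the core iff all 6 neighbours
        # are inside the lesion
        core_oracle = np.zeros_like(support)
        idx = np.argwhere(support)
        for i, j, k in idx:
            ok = True
            for di, dj, dk in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
                ii, jj, kk = i + di, j + dj, k + dk
                if not (
                    0 <= ii < support.shape[0]
                    and 0 <= jj < support.shape[1]
                    and 0 <= kk < support.shape[2]
                    and support[ii, jj, kk]
                ):
                    ok = False
                    break
            core_oracle[i, j, k] = ok
        assert np.array_equal(lesion.subtype_masks["core"] > 0, core_oracle)

    def test_rim_and_core_partition_lesion(self, grid):
        lesion = generate_lesion_mask(LesionSpec("lobulated", 15.0, (32, 32, 16), seed=1), grid)
        assign_rim_enhancement(lesion, 1)
        rim, core = lesion.subtype_masks["rim"], lesion.subtype_masks["core"]
        assert not np.any((rim > 0) & (core > 0))
        np.testing.assert_allclose(rim + core, lesion.mask)

    def test_thickness_exceeding_radius_raises(self, grid):
        lesion = generate_lesion_mask(
            LesionSpec("round", 8.0, (32, 32, 16), seed=0, n_spheres=1), grid
        )
        with pytest.raises(ValueError, match="thickness"):
            assign_rim_enhancement(lesion, 10)


class TestHeterogeneousEnhancement:
    def test_single_label_homogeneous(self, grid):
        lesion = generate_lesion_mask(LesionSpec("round", 12.0, (32, 32, 16), seed=0), grid)
        assign_heterogeneous_enhancement(lesion, ["core"], [1.0], seed=0)
        np.testing.assert_allclose(lesion.subtype_masks["core"], lesion.mask)

    def test_realized_fractions(self):
        # finer grid so the lesion holds >= 500 voxels
        grid = VoxelGrid((64, 64, 64), (64.0, 64.0, 64.0))
        lesion = generate_lesion_mask(LesionSpec("round", 14.0, (32, 32, 32), seed=0), grid)
        n = (lesion.mask > 0).sum()
        assert n >= 500
        assign_heterogeneous_enhancement(lesion, ["a", "b"], [0.5, 0.5], seed=1)
        fa = (lesion.subtype_masks["a"] > 0).sum() / n
        assert abs(fa - 0.5) <= 0.05

    def test_deterministic_and_fraction_sum_checked(self, grid):
        lesion = generate_lesion_mask(LesionSpec("round", 12.0, (32, 32, 16), seed=0), grid)
        assign_heterogeneous_enhancement(lesion, ["a", "b"], [0.3, 0.7], seed=4)
        first = {k: v.copy() for k, v in lesion.subtype_masks.items()}
        assign_heterogeneous_enhancement(lesion, ["a", "b"], [0.3, 0.7], seed=4)
        for k in first:
            assert np.array_equal(first[k], lesion.subtype_masks[k])
        with pytest.raises(ValueError, match="sum"):
            assign_heterogeneous_enhancement(lesion, ["a", "b"], [0.3, 0.6], seed=0)


class TestInsertion:
    def test_empty_lesion_leaves_model_unchanged(self, fresh_phantom, grid):
        from breastdro.lesions import Lesion

        before = fresh_phantom.tissue_class("water").base_image.copy()
        empty = Lesion(mask=np.zeros(grid.matrix_size), subtype_masks={})
        insert_lesion(fresh_phantom, empty, seed=0)
        assert np.array_equal(fresh_phantom.tissue_class("water").base_image, before)

    def test_grayscale_matches_fibroglandular_stats(self, fresh_phantom, grid):
        water = fresh_phantom.tissue_class("water")
        fib_mean = water.base_image[water.subtype("fibroglandular").mask > 0.5].mean()
        lesion = generate_lesion_mask(LesionSpec("round", 14.0, (20, 36, 16), seed=2), grid)
        insert_lesion(fresh_phantom, lesion, seed=3)
        lesion_mean = lesion.grayscale_values.mean()
        assert abs(lesion_mean - fib_mean) / fib_mean <= 0.05

    def test_spiculated_2cm_inserts_and_displaces_fat(self, fresh_phantom, grid):
        spec = LesionSpec(
            "spiculated",
            20.0,
            (20, 36, 16),
            seed=5,
            rim_thickness_voxels=1,
            subtype_params={
                "rim": KineticParams(0.5, 0.3, 0.0),
                "core": KineticParams(0.08, 0.4, 0.0),
            },
        )
        lesion = generate_lesion_mask(spec, grid)
        assign_rim_enhancement(lesion, 1)
        model = insert_lesion(fresh_phantom, lesion, seed=6)
        fat = model.tissue_class("fat")
        assert np.all(fat.subtypes[0].mask[lesion.binary_mask] == 0)
        water = model.tissue_class("water")
        names = {st.name for st in water.subtypes}
        assert {"lesion_rim", "lesion_core"} <= names
        assert water.subtype("lesion_rim").kinetic_params.ktrans_per_min == 0.5
        # partition still holds after insertion
        assert water.subtype_mask_sum().max() <= 1 + 1e-6

    def test_error_without_fibroglandular_statistics(self, grid):
        from breastdro.anatomy import assign_water_subtypes, load_anatomy

        model = load_anatomy(np.ones(grid.matrix_size), np.ones(grid.matrix_size), grid)
        model = assign_water_subtypes(model, {"fibroglandular": np.zeros(grid.matrix_size)})
        lesion = generate_lesion_mask(LesionSpec("round", 10.0, (32, 32, 16), seed=0), grid)
        with pytest.raises(ValueError, match="fibroglandular"):
            insert_lesion(model, lesion, seed=0)
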