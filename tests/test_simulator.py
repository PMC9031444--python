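import numpy as np
import pytest

from breastdro.analysis import measure_snr, reference_recon
from breastdro.kinetics import KineticParams, biexponential_vif, tabulated_vif
from breastdro.mri import ScanProtocol, build_cartesian_pattern, spectral_weight, spgr_signal
from breastdro.simulator import (
    NoiseSpec,
    SimulationJob,
    simulate,
    static_image_weighting,
)


@pytest.fixture(scope="module")
def pattern(grid):
    return build_cartesian_pattern(grid.matrix_size, 7.8, 2.2)


@pytest.fixture(scope="module")
def static_job(phantom, protocol, pattern):
    return SimulationJob(anatomy=phantom, protocol=protocol, frames=[pattern])


def weighted_reference(job, te_ms=2.2):
    """Expected reconstruction: per-class spectrally weighted T1-weighted image."""
    w = static_image_weighting(job)
    ref = np.zeros(job.anatomy.grid.matrix_size, dtype=complex)
    for cls, st in job.anatomy.iter_subtypes():
        sw = spectral_weight(cls.spectral_model, te_ms, job.protocol.field_strength_T)
        ref += w[f"{cls.name}/{st.name}"][0] * sw
    return ref


class TestStaticWeighting:
    def test_zero_base_image_gives_zero(self, phantom, protocol, pattern):
        import copy

        model = copy.deepcopy(phantom)
        for cls in model.classes:
            cls.base_image = np.zeros_like(cls.base_image)
        job = SimulationJob(anatomy=model, protocol=protocol, frames=[pattern])
        for img in static_image_weighting(job).values():
            assert np.all(img == 0)

    def test_fat_fibroglandular_ratio_follows_signal_equation(self, static_job):
        w = static_image_weighting(static_job)
        fat = w["fat/fat"][0]
        fib = w["water/fibroglandular"][0]
        model = static_job.anatomy
        vox = np.argwhere(
            (model.tissue_class("fat").subtypes[0].mask > 0.2)
            & (model.tissue_class("water").subtype("fibroglandular").mask > 0.2)
        )
        assert len(vox) > 0
        i, j, k = vox[0]
        expected = spgr_signal(1.0, 10.0, 7.8, 296.0) / spgr_signal(1.0, 10.0, 7.8, 1266.0)
        fat_content = model.tissue_class("fat").subtypes[0].mask[i, j, k]
        fib_content = model.tissue_class("water").subtype("fibroglandular").mask[i, j, k]
        got = (fat[i, j, k].real / fat_content) / (fib[i, j, k].real / fib_content)
        assert np.isclose(got, expected, rtol=1e-10)

    def test_equal_t1_subtypes_merge_linearly(self, phantom, protocol, pattern):
        """Splitting a mask into two equal-T1 subtypes must not change the sum."""
        import copy

        model = copy.deepcopy(phantom)
        water = model.tissue_class("water")
        fib = water.subtype("fibroglandular")
        half_a = fib.mask * 0.5
        from breastdro.anatomy import TissueSubtype

        water.subtypes = [s for s in water.subtypes if s.name != "fibroglandular"] + [
            TissueSubtype("fib_a", half_a, t1_ms=fib.t1_ms),
            TissueSubtype("fib_b", fib.mask - half_a, t1_ms=fib.t1_ms),
        ]
        job_split = SimulationJob(anatomy=model, protocol=protocol, frames=[pattern])
        w_split = static_image_weighting(job_split)
        job_ref = SimulationJob(anatomy=phantom, protocol=protocol, frames=[pattern])
        w_ref = static_image_weighting(job_ref)
        merged = w_split["water/fib_a"] + w_split["water/fib_b"]
        np.testing.assert_allclose(merged, w_ref["water/fibroglandular"], atol=1e-12)


class TestFullSamplingRoundTrip:
    def test_inverse_fft_reproduces_weighted_anatomy(self, static_job):
        vol = reference_recon(simulate(static_job))[0]
        ref = weighted_reference(static_job)
        assert np.abs(vol - ref).max() / np.abs(ref).max() < 1e-6

    def test_linearity_over_tissue_classes(self, phantom, protocol, pattern):
        import copy

        both = simulate(SimulationJob(anatomy=phantom, protocol=protocol, frames=[pattern]))
        fat_only = copy.deepcopy(phantom)
        fat_only.tissue_class("water").base_image = np.zeros(phantom.grid.matrix_size)
        water_only = copy.deepcopy(phantom)
        water_only.tissue_class("fat").base_image = np.zeros(phantom.grid.matrix_size)
        a = simulate(SimulationJob(anatomy=fat_only, protocol=protocol, frames=[pattern]))
        b = simulate(SimulationJob(anatomy=water_only, protocol=protocol, frames=[pattern]))
        np.testing.assert_allclose(
            both.frames[0], a.frames[0] + b.frames[0], rtol=0, atol=1e-9
        )


class TestDynamicWeights:
    def test_truth_mode_equals_frame_mode_for_constant_enhancement(
        self, fresh_phantom, protocol, pattern
    ):
        vif = tabulated_vif([0.0, 1e4], [1.0, 1.0])
        water = fresh_phantom.tissue_class("water")
        water.subtype("fibroglandular").kinetic_params = KineticParams(0.0, 0.0, 0.5)
        frame = simulate(
            SimulationJob(anatomy=fresh_phantom, protocol=protocol, frames=[pattern], vif=vif)
        )
        truth = simulate(
            SimulationJob(
                anatomy=fresh_phantom,
                protocol=protocol,
                frames=[pattern],
                vif=vif,
                truth_mode=True,
            )
        )
        np.testing.assert_allclose(frame.frames[0], truth.frames[0], rtol=1e-10)

    def test_truth_mode_single_scale_per_frame(self, fresh_phantom, protocol, pattern):
        from breastdro.simulator import _subtype_dynamic_weights

        vif = biexponential_vif()
        water = fresh_phantom.tissue_class("water")
        st = water.subtype("fibroglandular")
        st.kinetic_params = KineticParams(0.2, 0.4, 0.0)
        job = SimulationJob(
            anatomy=fresh_phantom, protocol=protocol, frames=[pattern], vif=vif, truth_mode=True
        )
        w = _subtype_dynamic_weights(water, st, pattern, job, 0)
        assert np.unique(np.round(w, 14)).size == 1

    def test_opposed_phase_cancellation_at_fat_water_interface(self, phantom):
        """Mixed fat/water voxels lose magnitude at the opposed-phase TE
        relative to the in-phase TE (the India-ink artifact)."""
        vols = {}
        for te in (2.2, 4.2):
            proto = ScanProtocol(te_ms=(te,))
            pat = build_cartesian_pattern(phantom.grid.matrix_size, 7.8, te)
            vols[te] = reference_recon(
                simulate(SimulationJob(anatomy=phantom, protocol=proto, frames=[pat]))
            )[0]
        fat = phantom.tissue_class("fat").subtypes[0].mask
        fib = phantom.tissue_class("water").subtype("fibroglandular").mask
        mixed = (fat > 0.3) & (fat < 0.7) & (fib > 0.3)
        assert mixed.sum() > 10
        assert np.abs(vols[2.2])[mixed].mean() < np.abs(vols[4.2])[mixed].mean()

    def test_fat_saturation_suppresses_fat_signal(self, phantom):
        """The standard inversion-recovery variant suppresses fat while
        leaving water-dominated voxels intact (the compact as_printed form
        drops a term and does not suppress at flips above 90 degrees)."""
        from breastdro.mri import FatSatSettings

        pat = build_cartesian_pattern(phantom.grid.matrix_size, 7.8, 4.2)
        base = ScanProtocol(te_ms=(4.2,))
        sat = ScanProtocol(
            te_ms=(4.2,),
            fatsat=FatSatSettings(tr_ir_ms=500.0, alpha_ir_deg=100.0, formula="standard_ir"),
        )
        v0 = reference_recon(simulate(SimulationJob(anatomy=phantom, protocol=base, frames=[pat])))[0]
        v1 = reference_recon(simulate(SimulationJob(anatomy=phantom, protocol=sat, frames=[pat])))[0]
        fat_vox = phantom.tissue_class("fat").subtypes[0].mask > 0.9
        fib_vox = phantom.tissue_class("water").subtype("fibroglandular").mask > 0.9
        fat_ratio = np.abs(v1)[fat_vox].mean() / np.abs(v0)[fat_vox].mean()
        fib_ratio = np.abs(v1)[fib_vox].mean() / np.abs(v0)[fib_vox].mean()
        assert fat_ratio < 0.7
        assert fat_ratio < fib_ratio
        assert fib_ratio > 0.9


class TestNoise:
    def test_no_noise_is_exact_sum(self, static_job):
        ds = simulate(static_job)
        assert np.all(np.isfinite(ds.frames[0]))
        ds2 = simulate(static_job)
        np.testing.assert_array_equal(ds.frames[0], ds2.frames[0])

    def test_target_snr_30_measures_back(self, phantom, protocol, pattern):
        from scipy import ndimage

        breast = phantom.breast_mask()
        background = ~ndimage.binary_dilation(breast, iterations=3)
        measured = []
        for seed in range(10):
            job = SimulationJob(
                anatomy=phantom,
                protocol=protocol,
                frames=[pattern],
                noise=NoiseSpec(target_snr=30.0, seed=seed),
            )
            vol = reference_recon(simulate(job))[0]
            measured.append(measure_snr(np.abs(vol), breast, background))
        assert 27.0 <= np.mean(measured) <= 33.0

    def test_noise_variance_scales_inversely_with_snr(self, phantom, protocol, pattern):
        clean = simulate(
            SimulationJob(anatomy=phantom, protocol=protocol, frames=[pattern])
        ).frames[0]
        noises = {}
        for snr in (30.0, 15.0):
            job = SimulationJob(
                anatomy=phantom,
                protocol=protocol,
                frames=[pattern],
                noise=NoiseSpec(target_snr=snr, seed=0),
            )
            noises[snr] = simulate(job).frames[0] - clean
        ratio = np.var(noises[15.0].real) / np.var(noises[30.0].real)
        assert abs(ratio - 4.0) < 0.2

    def test_noise_components_uncorrelated_equal_variance(self, phantom, protocol, pattern):
        clean = simulate(
            SimulationJob(anatomy=phantom, protocol=protocol, frames=[pattern])
        ).frames[0]
        job = SimulationJob(
            anatomy=phantom,
            protocol=protocol,
            frames=[pattern],
            noise=NoiseSpec(target_snr=30.0, seed=1),
        )
        n = (simulate(job).frames[0] - clean).ravel()
        vr, vi = np.var(n.real), np.var(n.imag)
        assert abs(vr / vi - 1.0) < 0.05
        corr = np.corrcoef(n.real, n.imag)[0, 1]
        assert abs(corr) < 0.05

    def test_noise_deterministic_given_seed(self, phantom, protocol, pattern):
        job = SimulationJob(
            anatomy=phantom,
            protocol=protocol,
            frames=[pattern],
            noise=NoiseSpec(target_snr=30.0, seed=3),
        )
        np.testing.assert_array_equal(simulate(job).frames[0], simulate(job).frames[0])

    def test_invalid_snr_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(target_snr=0.0)


class TestMultiCoil:
    def test_uniform_single_coil_matches_no_coil(self, phantom, protocol, pattern):
        from breastdro.mri import CoilSensitivities

        uniform = CoilSensitivities(maps=np.ones((1,) + phantom.grid.matrix_size, complex))
        a = simulate(SimulationJob(anatomy=phantom, protocol=protocol, frames=[pattern]))
        b = simulate(
            SimulationJob(anatomy=phantom, protocol=protocol, frames=[pattern], coils=uniform)
        )
        np.testing.assert_allclose(a.frames[0], b.frames[0], rtol=1e-12)

    def test_channel_count_and_rss_recon(self, phantom, protocol, pattern, grid):
        from breastdro.mri import simulate_coil_maps

        coils = simulate_coil_maps(grid, 4, geometry_seed=0)
        ds = simulate(
            SimulationJob(anatomy=phantom, protocol=protocol, frames=[pattern], coils=coils)
        )
        assert ds.frames[0].shape == (4, pattern.n_samples)
        vol = reference_recon(ds)[0]
        assert vol.dtype.kind == "f"  # RSS magnitude
        assert np.all(vol[phantom.breast_mask()] > 0)


def test_hdf5_export_round_trips(static_job, tmp_path):
    import h5py

    ds = simulate(static_job)
    path = tmp_path / "k.h5"
    ds.to_hdf5(path)
    with h5py.File(path) as h5:
        data = h5["kspace/frame0/channel0"][...]
        assert data.shape == (static_job.frames[0].n_samples,)
        np.testing.assert_allclose(data, ds.frames[0][0].astype(np.complex64))
        assert "truth" in h5 and "pattern/frame0/coords" in h5
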