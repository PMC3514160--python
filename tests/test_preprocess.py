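import numpy as np
import pytest

from tpm3d import generate_phantom, make_preset
from tpm3d.datamodel import SegmentModel, ValidationError
from tpm3d.phantom import PhantomConfig
from tpm3d.preprocess import (
    assign_segments,
    correct_background_phase,
    decompose_local,
    interpolate_curve,
)


def _static_phantom(plane=None, noise=0.0, seed=0):
    return PhantomConfig(
        n_slices=3, n_phases=5, grid_size=48,
        endo_contraction_frac=0.0, epi_contraction_frac=0.0,
        rotation_apex_deg=0.0, rotation_base_deg=0.0,
        long_excursion_apex_mm=0.0, long_excursion_base_mm=0.0,
        background_plane=plane, noise_sd_cm_s=noise, seed=seed,
    )


class TestBackgroundCorrection:
    def test_injected_plane_removed_exactly_without_noise(self):
        plane = (1.0, 0.01, -0.02)
        ds, _ = generate_phantom(_static_phantom(plane=plane))
        out = correct_background_phase(ds)
        stat = out.static_mask[0]
        assert np.abs(out.velocities[:, :, 0][:, :, stat]).max() < 1e-10
        # whole slice corrected, not only static tissue
        assert np.abs(out.velocities).max() < 1e-10

    def test_zero_background_leaves_dataset_unchanged(self):
        ds, _ = generate_phantom(make_preset(
            "healthy", n_slices=3, grid_size=48, noise_sd_cm_s=0.0,
            background_plane=None))
        out = correct_background_phase(ds)
        assert np.abs(out.velocities - ds.velocities).max() < 1e-10

    def test_coefficients_recovered_within_three_standard_errors(self):
        plane = (1.0, 0.01, -0.02)
        sd = 0.2
        ds, _ = generate_phantom(_static_phantom(plane=plane, noise=sd, seed=3))
        out = correct_background_phase(ds)
        x, y = ds.inplane_coords_mm()
        stat = ds.static_mask[0]
        design = np.column_stack([np.ones(stat.sum()), x[stat], y[stat]])
        cov = sd**2 * np.linalg.inv(design.T @ design)
        se = np.sqrt(np.diag(cov))
        err = np.abs(out.background_coefficients - np.array(plane))
        assert np.all(err[:, 0, 0] <= 3.0 * se)   # one fit per component
        # and across all fits the vast majority agree at 3 SE
        assert (err <= 3.0 * se).mean() > 0.95

    def test_correction_is_idempotent(self):
        ds, _ = generate_phantom(make_preset(
            "healthy", n_slices=3, grid_size=48, seed=5))
        once = correct_background_phase(ds)
        twice = correct_background_phase(once)
        assert np.abs(twice.velocities - once.velocities).max() < 1e-9
        assert np.abs(twice.background_coefficients).max() < 1e-9

    def test_too_few_static_voxels_rejected(self):
        ds, _ = generate_phantom(_static_phantom())
        ds.static_mask[:] = False
        ds.static_mask[:, 0, :3] = True
        with pytest.raises(ValidationError, match="static voxels"):
            correct_background_phase(ds)

    def test_collinear_static_voxels_fall_back_to_offset(self):
        plane = (0.7, 0.0, 0.0)
        ds, _ = generate_phantom(_static_phantom(plane=plane))
        ds.static_mask[:] = False
        ds.static_mask[:, 0, :] = True        # a single row: collinear
        with pytest.warns(UserWarning, match="collinear"):
            out = correct_background_phase(ds)
        assert np.allclose(out.background_coefficients[:, :, :, 0], 0.7)
        assert np.allclose(out.background_coefficients[:, :, :, 1:], 0.0)


class TestDecomposeLocal:
    def test_energy_preserved_per_voxel(self):
        ds, _ = generate_phantom(make_preset(
            "healthy", n_slices=3, grid_size=48, seed=2))
        f = decompose_local(ds)
        m = f.mask
        e_local = f.v_l[m] ** 2 + f.v_r[m] ** 2 + f.v_c[m] ** 2
        vx, vy, vz = ds.velocities
        e_cart = vx[m] ** 2 + vy[m] ** 2 + vz[m] ** 2
        assert np.allclose(e_local, e_cart, rtol=1e-10, atol=1e-12)

    def test_pure_contraction_appears_radial_only(self):
        cfg = PhantomConfig(
            n_slices=3, n_phases=10, grid_size=48, phase_interval_ms=90.0,
            rotation_apex_deg=0.0, rotation_base_deg=0.0,
            long_excursion_apex_mm=0.0, long_excursion_base_mm=0.0,
        )
        ds, _ = generate_phantom(cfg)
        f = decompose_local(ds)
        p = 3  # mid-systole
        m = f.mask[p, 1]
        assert f.v_r[p, 1][m].mean() > 0.5       # systolic inward positive
        assert np.abs(f.v_c[p, 1][m]).max() < 1e-9

    def test_pure_clockwise_rotation_appears_circumferential_only(self):
        cfg = PhantomConfig(
            n_slices=2, n_phases=4, grid_size=48, constant_omega_deg_s=50.0,
            endo_contraction_frac=0.0, epi_contraction_frac=0.0,
            long_excursion_apex_mm=0.0, long_excursion_base_mm=0.0,
        )
        ds, _ = generate_phantom(cfg)
        f = decompose_local(ds)
        m = f.mask[0, 0]
        assert np.all(f.v_c[0, 0][m] > 0)
        assert np.abs(f.v_r[0, 0][m]).max() < 1e-9

    def test_rigid_translation_has_zero_slice_mean_radial_velocity(self):
        ds, _ = generate_phantom(_static_phantom())
        ds.velocities[0] = np.where(ds.myo_mask, 1.3, 0.0)   # uniform +x motion
        ds.velocities[1] = np.where(ds.myo_mask, -0.4, 0.0)
        f = decompose_local(ds)
        m = f.mask[0, 0]
        assert abs(f.v_r[0, 0][m].mean()) < 0.02   # inward and outward cancel

    def test_longitudinal_positive_toward_apex(self):
        ds, _ = generate_phantom(_static_phantom())
        ds.velocities[2] = np.where(ds.myo_mask, -2.0, 0.0)  # toward apex (-z)
        f = decompose_local(ds)
        assert np.all(f.v_l[f.mask] == 2.0)


class TestAssignSegments:
    def test_segments_partition_the_myocardium_every_phase(self):
        ds, _ = generate_phantom(make_preset("healthy", n_slices=3, grid_size=48, seed=1))
        f = decompose_local(ds)
        assign_segments(f, SegmentModel.standard(24))
        ids = f.segment_ids[24]
        for p in range(ds.meta.n_phases):
            for s in range(3):
                n_voxels = f.mask[p, s].sum()
                assert (ids[p, s] >= 0).sum() == n_voxels
                counts = np.bincount(ids[p, s][ids[p, s] >= 0], minlength=24)
                assert counts.sum() == n_voxels

    def test_uniform_annulus_has_balanced_segment_counts(self):
        ds, _ = generate_phantom(_static_phantom())
        f = decompose_local(ds)
        assign_segments(f, SegmentModel.standard(6))
        ids = f.segment_ids[6][0, 0]
        counts = np.bincount(ids[ids >= 0], minlength=6)
        # brute-force rasterization oracle: each 60-deg sector of the annulus
        x, y = ds.inplane_coords_mm()
        th = np.degrees(np.arctan2(x, y)) % 360.0
        expected = [
            ((f.mask[0, 0]) & (th >= 60 * k) & (th < 60 * (k + 1))).sum()
            for k in range(6)
        ]
        assert np.array_equal(counts, expected)
        assert counts.max() - counts.min() <= max(4, 0.1 * counts.mean())


class TestInterpolateCurve:
    def test_constant_samples_give_constant_curve(self):
        t = np.arange(6) * 40.0
        c = interpolate_curve(t, np.full(6, 3.7), factor=8)
        assert np.allclose(c.values, 3.7)

    def test_sine_resampled_accurately(self):
        T = 1000.0
        t = np.linspace(0, T, 25)
        c = interpolate_curve(t, np.sin(2 * np.pi * t / T), factor=8)
        truth = np.sin(2 * np.pi * c.time_ms / T)
        assert np.abs(c.values - truth).max() < 1e-3

    def test_factor_one_preserves_sample_values(self):
        t = np.arange(5) * 10.0
        v = np.array([0.0, 2.0, -1.0, 4.0, 1.0])
        c = interpolate_curve(t, v, factor=1)
        assert np.allclose(c.values, v)

    def test_curve_passes_through_samples_at_any_factor(self):
        t = np.arange(7) * 37.3
        v = np.sin(t / 100.0)
        c = interpolate_curve(t, v, factor=4)
        assert np.allclose(c.values[::4], v, atol=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError, match="4 samples"):
            interpolate_curve([0.0, 1.0, 2.0], [1.0, 2.0, 3.0], factor=2)
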