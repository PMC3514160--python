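import numpy as np
import pytest

from helpers import ring_field
from tpm3d import generate_phantom
from tpm3d.datamodel import SegmentModel, TrackedPoints
from tpm3d.kinematics import (
    contour_radius_at,
    rotation_angle_curve,
    strain_curves,
    torsion_rate_curve,
    track_displacement,
)
from tpm3d.phantom import PhantomConfig
from tpm3d.preprocess import assign_segments, decompose_local


def _tracked_and_field(cfg, model=None):
    ds, truth = generate_phantom(cfg)
    field = decompose_local(ds)
    model = model or SegmentModel.standard(6)
    assign_segments(field, model)
    return track_displacement(field, model), field, truth


class TestTrackDisplacement:
    def test_constant_velocity_displaces_points_linearly(self):
        # 2 cm/s for 5 steps of 40 ms -> 4 mm along +x
        cfg = PhantomConfig(
            n_slices=2, n_phases=6, grid_size=96, voxel_mm=1.5,
            phase_interval_ms=40.0,
            endo_contraction_frac=0.0, epi_contraction_frac=0.0,
            rotation_apex_deg=0.0, rotation_base_deg=0.0,
            long_excursion_apex_mm=0.0, long_excursion_base_mm=0.0,
        )
        ds, _ = generate_phantom(cfg)
        ds.velocities[0] = np.where(ds.myo_mask, 2.0, 0.0)
        field = decompose_local(ds)
        model = SegmentModel.standard(24)   # centers align with velocity bins
        assign_segments(field, model)
        tracked = track_displacement(field, model)
        disp = tracked.center[..., -1, :] - tracked.center[..., 0, :]
        # the along-motion displacement follows x = n*v*dt; transverse error
        # is bounded by the angular-bin half width (a translating point may
        # sit up to 7.5 deg from the bin whose polar-decomposed velocity it
        # is advanced with, rotating the reconstructed vector by that much)
        assert np.allclose(disp[..., 0], 4.0, atol=0.15)
        assert np.abs(disp[..., 1]).max() <= 4.0 * np.sin(np.deg2rad(7.5))

    def test_zero_velocity_keeps_points_fixed(self):
        cfg = PhantomConfig(
            n_slices=2, n_phases=5, grid_size=32,
            endo_contraction_frac=0.0, epi_contraction_frac=0.0,
            rotation_apex_deg=0.0, rotation_base_deg=0.0,
            long_excursion_apex_mm=0.0, long_excursion_base_mm=0.0,
        )
        tracked, _, _ = _tracked_and_field(cfg)
        for name in ("center", "chord_a", "chord_b", "endo", "epi"):
            pts = getattr(tracked, name)
            assert np.array_equal(pts, np.repeat(pts[:, :, :1], 5, axis=2))

    def test_rigid_rotation_recovered_within_euler_bound(self):
        # 90 deg/s, dt = 10 ms, 100 steps -> 90 deg; per-step chord error
        # |atan(d) - d| ~ d^3/3 with d = omega*dt accumulates over N steps
        cfg = PhantomConfig(
            n_slices=2, n_phases=101, grid_size=64, phase_interval_ms=10.0,
            constant_omega_deg_s=90.0,
            endo_contraction_frac=0.0, epi_contraction_frac=0.0,
            long_excursion_apex_mm=0.0, long_excursion_base_mm=0.0,
            rotation_apex_deg=0.0, rotation_base_deg=0.0,
        )
        tracked, field, _ = _tracked_and_field(cfg)
        alpha, _ = rotation_angle_curve(tracked, field)
        delta = np.deg2rad(90.0 * 0.010)
        bound_deg = np.degrees(100 * delta**3 / 3.0)
        assert np.all(np.abs(alpha[:, -1] - 90.0) <= 3 * bound_deg + 0.05)

    def test_scaling_velocities_scales_the_first_displacement_exactly(self):
        cfg = PhantomConfig(n_slices=2, n_phases=6, grid_size=48,
                            phase_interval_ms=150.0, noise_sd_cm_s=0.0)
        ds, _ = generate_phantom(cfg)
        model = SegmentModel.standard(6)

        def first_step(scale):
            d = ds.copy()
            d.velocities = d.velocities * scale
            f = decompose_local(d)
            assign_segments(f, model)
            tr = track_displacement(f, model)
            return tr.center[:, :, 1, :] - tr.center[:, :, 0, :]

        assert np.allclose(first_step(0.5), 0.5 * first_step(1.0), atol=1e-12)

    def test_points_leaving_the_grid_are_frozen_and_flagged(self):
        cfg = PhantomConfig(
            n_slices=1, n_phases=40, grid_size=24, voxel_mm=3.0,
            endo_radius_apex_mm=14.0, endo_radius_base_mm=14.0,
            wall_thickness_apex_mm=7.0, wall_thickness_base_mm=7.0,
            static_border_vox=1, phase_interval_ms=40.0,
            endo_contraction_frac=0.0, epi_contraction_frac=0.0,
            rotation_apex_deg=0.0, rotation_base_deg=0.0,
            long_excursion_apex_mm=0.0, long_excursion_base_mm=0.0,
        )
        ds, _ = generate_phantom(cfg)
        ds.velocities[0] = np.where(ds.myo_mask, 15.0, 0.0)  # races off the FOV
        field = decompose_local(ds)
        model = SegmentModel.standard(6)
        assign_segments(field, model)
        tracked = track_displacement(field, model)
        assert tracked.truncated.any()
        assert tracked.provenance["n_truncated"] > 0
        assert np.isfinite(tracked.center).all()


class TestRotationAngle:
    def test_no_rotation_gives_identically_zero_angle(self):
        cfg = PhantomConfig(
            n_slices=2, n_phases=8, grid_size=48, phase_interval_ms=120.0,
            rotation_apex_deg=0.0, rotation_base_deg=0.0,
            long_excursion_apex_mm=0.0, long_excursion_base_mm=0.0,
        )
        tracked, field, _ = _tracked_and_field(cfg)
        alpha, _ = rotation_angle_curve(tracked, field)
        assert np.abs(alpha).max() < 1e-6

    def test_healthy_twist_recovered_against_discrete_integral_oracle(self, healthy_clean):
        """Tracking matches the Euler sum of the true angular velocity."""
        cfg, curves, truth = (healthy_clean[k] for k in ("cfg", "curves", "truth"))
        w = cfg.waveform()
        t = np.arange(cfg.n_phases) * cfg.phase_interval_ms
        dg = w.dg(t)
        alpha_oracle = np.array([
            amp * np.concatenate([[0.0], np.cumsum(dg[:-1]) * cfg.phase_interval_ms])
            for amp in cfg.rotation_amp()
        ])
        assert np.abs(curves.rotation_deg - alpha_oracle).max() < 0.5

    def test_apex_and_base_rotate_oppositely_in_systole(self, healthy_clean):
        curves = healthy_clean["curves"]
        alpha = curves.rotation_deg
        i_peak = np.argmax(np.abs(alpha[0]))
        assert alpha[0, i_peak] * alpha[-1, i_peak] < 0


class TestTorsionRate:
    def test_formula_on_counter_rotating_rings(self):
        # omega_apex = +30, omega_base = -30 deg/s, d = 6 cm
        field = ring_field([30.0, -30.0], slice_gap_mm=60.0)
        torsion = torsion_rate_curve(field)
        r_mean_cm = field.radius_mm[0, 0][field.mask[0, 0]].mean() / 10.0
        expected = 60.0 * (2 * r_mean_cm) / (2 * 6.0)
        assert np.allclose(torsion, expected, rtol=1e-9)
        # with exactly 3 cm mean radius the printed example gives 30
        assert abs(expected - 30.0) < 1.0

    def test_rigid_global_rotation_has_zero_torsion(self):
        field = ring_field([45.0, 45.0, 45.0])
        assert np.allclose(torsion_rate_curve(field), 0.0, atol=1e-12)

    def test_single_slice_rejected(self):
        field = ring_field([30.0])
        with pytest.raises(Exception, match="slice"):
            torsion_rate_curve(field, apex_slice=0, base_slice=0)


def _synthetic_points(radii, n_seg=6, n_ph=2, transform=None):
    """TrackedPoints on concentric circles; phase 1 transformed."""
    th = np.deg2rad((np.arange(n_seg) + 0.5) * 360.0 / n_seg)
    model = SegmentModel.standard(n_seg)

    def circle(r, ang):
        return np.stack([r * np.sin(ang), r * np.cos(ang)], axis=-1)

    width = 2 * np.pi / n_seg
    base = {
        "center": circle(radii["mid"], th),
        "chord_a": circle(radii["mid"], th - 0.45 * width),
        "chord_b": circle(radii["mid"], th + 0.45 * width),
        "endo": circle(radii["endo"], th),
        "epi": circle(radii["epi"], th),
    }
    pts = {}
    for name, p0 in base.items():
        arr = np.zeros((1, n_seg, n_ph, 2))
        arr[0, :, 0] = p0
        for p in range(1, n_ph):
            arr[0, :, p] = transform(p0) if transform else p0
        pts[name] = arr
    return TrackedPoints(model=model, truncated=np.zeros((1, n_seg), bool), **pts)


class TestStrain:
    def test_uniform_scaling_gives_exact_similarity_strain(self):
        tracked = _synthetic_points(
            {"mid": 30.0, "endo": 25.0, "epi": 35.0}, transform=lambda p: 0.8 * p
        )
        s = strain_curves(tracked)
        assert np.allclose(s["circumferential"][..., 1], -20.0, atol=1e-12)
        assert np.allclose(s["radial"][..., 1], -20.0, atol=1e-12)
        assert np.allclose(s["circumferential"][..., 0], 0.0)

    def test_rigid_rotation_is_strain_free(self):
        c, s_ = np.cos(np.deg2rad(30)), np.sin(np.deg2rad(30))
        rot = np.array([[c, -s_], [s_, c]])
        tracked = _synthetic_points(
            {"mid": 30.0, "endo": 25.0, "epi": 35.0}, transform=lambda p: p @ rot.T
        )
        s = strain_curves(tracked)
        assert np.abs(s["circumferential"][..., 1]).max() < 1e-9
        assert np.abs(s["radial"][..., 1]).max() < 1e-9

    def test_degenerate_chord_is_flagged(self):
        tracked = _synthetic_points({"mid": 0.01, "endo": 25.0, "epi": 35.0})
        s = strain_curves(tracked)
        assert np.isnan(s["circumferential"]).all()
        assert np.isfinite(s["radial"]).all()

    def test_incompressible_style_annulus_recovered_within_5_percent(self, healthy_clean):
        """Wall thickening (radial > 0) and shortening (circ < 0) match the
        closed-form annulus kinematics at peak contraction."""
        curves, truth = healthy_clean["curves"], healthy_clean["truth"]
        sc = curves.strain[("circumferential", 6)]
        sr = curves.strain[("radial", 6)]
        true_c = truth.circ_strain_pct
        true_r = truth.radial_strain_pct
        assert sc.min() < 0 < sr.max()
        err_c = np.abs(sc.min(axis=-1) - true_c.min(axis=-1))
        err_r = np.abs(sr.max(axis=-1) - true_r.max(axis=-1))
        assert err_c.max() <= 0.05 * np.abs(true_c.min())
        assert err_r.max() <= 0.05 * np.abs(true_r.max())

    def test_noise_free_cycle_closure_below_one_percent(self, healthy_clean):
        sc = healthy_clean["curves"].strain[("circumferential", 6)]
        sr = healthy_clean["curves"].strain[("radial", 6)]
        assert np.nanmax(np.abs(sc[..., -1])) < 1.0
        # the endo/epi pair spans the steepest transmural velocity gradient,
        # so its first-order (Euler) closure drift is somewhat larger
        assert np.nanmax(np.abs(sr[..., -1])) < 1.5


def test_contour_radius_interpolation_is_exact_on_circles():
    th = np.deg2rad(np.arange(0, 360, 5.0))
    contour = 27.0 * np.stack([np.sin(th), np.cos(th)], axis=-1)
    r = contour_radius_at(contour, np.zeros(2), np.array([3.0, 91.0, 359.0]))
    assert np.allclose(r, 27.0, atol=1e-6)
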