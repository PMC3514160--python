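"""Analytic beating left-ventricle phantom with known ground-truth kinematics.

The phantom models the LV myocardium as a stack of concentric annuli
(short-axis slices).  Per slice, the endo- and epicardial radii contract
and re-expand following a smooth two-lobe raised-cosine waveform, the
annulus rotates rigidly with a slice-dependent amplitude (opposite apical
and basal signs produce the systolic twist / diastolic untwist), and the
whole slice translates along the long axis with a base-to-apex gradient.
Voxel velocities are the analytic material velocities of this motion
sampled at voxel centers, optionally with per-segment activation delays
(applied as a time shift of the segment's velocity waveform), additive
Gaussian noise, and a per-slice linear background-phase plane affecting
myocardium and static tissue alike.

Because positions are defined analytically and return to their start after
one cycle, every downstream quantity (rotation angle, circumferential and
radial strain, per-segment velocities, activation onset times) has a
closed-form ground truth stored in :class:`PhantomTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .datamodel import (
    AcquisitionMeta,
    SegmentModel,
    ValidationError,
    VelocityDataset,
)

__all__ = [
    "TwoLobeWaveform",
    "PhantomConfig",
    "PhantomTruth",
    "generate_phantom",
    "make_preset",
    "PRESETS",
]

MM_PER_MS_TO_CM_PER_S = 100.0


@dataclass
class TwoLobeWaveform:
    """Smooth contraction shape g(t) in [0, 1] built from raised cosines.

    g rises from 0 to 1 over the systolic interval ``[0, t_sys_ms]``,
    relaxes back to 0 over ``(t_sys_ms, t_sys_ms + t_relax_ms]`` and stays
    at 0 during the remaining diastasis (resting phase).  Its derivative is
    continuous, zero at both lobe ends, and the corresponding velocity
    waveform has one positive systolic and one negative diastolic lobe.
    """

    t_sys_ms: float
    t_relax_ms: float
    cycle_ms: float

    def __post_init__(self):
        if self.t_sys_ms <= 0 or self.t_relax_ms <= 0:
            raise ValidationError("waveform lobe durations must be positive")
        if self.t_sys_ms + self.t_relax_ms > self.cycle_ms + 1e-9:
            raise ValidationError("waveform lobes exceed cycle length")

    def g(self, t_ms):
        t = np.mod(np.asarray(t_ms, dtype=float), self.cycle_ms)
        out = np.zeros_like(t)
        sys = t <= self.t_sys_ms
        out = np.where(sys, 0.5 * (1 - np.cos(np.pi * t / self.t_sys_ms)), out)
        rel = (~sys) & (t <= self.t_sys_ms + self.t_relax_ms)
        out = np.where(
            rel, 0.5 * (1 + np.cos(np.pi * (t - self.t_sys_ms) / self.t_relax_ms)), out
        )
        return out

    def dg(self, t_ms):
        """Time derivative of g in 1/ms."""
        t = np.mod(np.asarray(t_ms, dtype=float), self.cycle_ms)
        out = np.zeros_like(t)
        sys = t <= self.t_sys_ms
        out = np.where(
            sys, 0.5 * np.pi / self.t_sys_ms * np.sin(np.pi * t / self.t_sys_ms), out
        )
        rel = (~sys) & (t <= self.t_sys_ms + self.t_relax_ms)
        out = np.where(
            rel,
            -0.5 * np.pi / self.t_relax_ms
            * np.sin(np.pi * (t - self.t_sys_ms) / self.t_relax_ms),
            out,
        )
        return out

    def onset_time_ms(self, fraction: float) -> float:
        """Time at which g first reaches ``fraction`` of its peak (=1)."""
        return self.t_sys_ms / np.pi * np.arccos(1.0 - 2.0 * fraction)


@dataclass
class PhantomConfig:
    """Parameters of the analytic LV phantom.

    Geometry and sampling defaults emulate a volunteer-style protocol
    (25 phases at 37.3 ms, 21 slices of 3 mm isotropic voxels, VENC
    20 cm/s); motion amplitudes sit at physiological values: ~22%
    systolic endocardial radius excursion with wall thickening, +8 deg
    apical / -4 deg basal peak rotation (clockwise-positive, giving the
    normal twist), and 15 mm basal / 3 mm apical long-axis excursion.
    Per-segment activation delays and amplitude scales are indexed by the
    standard 6-segment model (clockwise from the image top:
    inferoseptal, inferior, inferolateral, anterolateral, anterior,
    anteroseptal).
    """

    n_slices: int = 21
    n_phases: int = 25
    grid_size: int = 128
    voxel_mm: float = 3.0
    phase_interval_ms: float = 37.3
    venc_cm_s: float = 20.0

    endo_radius_apex_mm: float = 14.0
    endo_radius_base_mm: float = 24.0
    wall_thickness_apex_mm: float = 7.0
    wall_thickness_base_mm: float = 9.0
    endo_contraction_frac: float = 0.22
    epi_contraction_frac: float = 0.08

    rotation_apex_deg: float = 8.0
    rotation_base_deg: float = -4.0
    constant_omega_deg_s: Optional[float] = None  # overrides the twist waveform

    long_excursion_apex_mm: float = 3.0
    long_excursion_base_mm: float = 15.0

    systole_fraction: float = 0.35
    relaxation_fraction: float = 0.30

    segment_delays_ms: tuple = (0.0,) * 6
    segment_amplitude_scale: tuple = (1.0,) * 6

    noise_sd_cm_s: float = 0.0
    background_plane: Optional[object] = None  # (a, b, c) broadcastable, cm/s & cm/s/mm
    static_border_vox: int = 4
    n_contour_points: int = 72
    angular_origin_deg: float = 0.0
    seed: int = 0

    # -- derived helpers --------------------------------------------------
    @property
    def cycle_ms(self) -> float:
        return self.n_phases * self.phase_interval_ms

    def waveform(self) -> TwoLobeWaveform:
        return TwoLobeWaveform(
            t_sys_ms=self.systole_fraction * self.cycle_ms,
            t_relax_ms=self.relaxation_fraction * self.cycle_ms,
            cycle_ms=self.cycle_ms,
        )

    def _linear_profile(self, apex, base) -> np.ndarray:
        if self.n_slices == 1:
            return np.array([apex], dtype=float)
        return apex + (base - apex) * np.arange(self.n_slices) / (self.n_slices - 1)

    def endo_radius0(self) -> np.ndarray:
        return self._linear_profile(self.endo_radius_apex_mm, self.endo_radius_base_mm)

    def epi_radius0(self) -> np.ndarray:
        return self.endo_radius0() + self._linear_profile(
            self.wall_thickness_apex_mm, self.wall_thickness_base_mm
        )

    def rotation_amp(self) -> np.ndarray:
        return self._linear_profile(self.rotation_apex_deg, self.rotation_base_deg)

    def long_amp(self) -> np.ndarray:
        return self._linear_profile(
            self.long_excursion_apex_mm, self.long_excursion_base_mm
        )

    def validate(self) -> "PhantomConfig":
        if self.n_phases < 3 or self.n_slices < 1:
            raise ValidationError("phantom needs >= 3 phases and >= 1 slice")
        if len(self.segment_delays_ms) != 6 or len(self.segment_amplitude_scale) != 6:
            raise ValidationError("segment delays/scales must have 6 entries")
        if max(self.segment_delays_ms) >= self.cycle_ms:
            raise ValidationError("segment delays must be shorter than the cycle")
        re0, rp0 = self.endo_radius0(), self.epi_radius0()
        re_min = re0 * (1 - self.endo_contraction_frac)
        rp_min = rp0 * (1 - self.epi_contraction_frac)
        if np.any(re_min >= rp_min) or np.any(re0 >= rp0):
            raise ValidationError(
                "contraction excursion makes the endocardial radius reach the "
                "epicardial radius"
            )
        half_fov = self.grid_size * self.voxel_mm / 2.0
        if rp0.max() >= half_fov - self.static_border_vox * self.voxel_mm:
            raise ValidationError("epicardium does not fit inside the static border")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["background_plane"] is not None:
            d["background_plane"] = np.asarray(d["background_plane"]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        for key in ("segment_delays_ms", "segment_amplitude_scale"):
            if key in d:
                d[key] = tuple(float(v) for v in d[key])
        return cls(**d)


@dataclass
class PhantomTruth:
    """Closed-form ground truth of a generated phantom.

    Arrays are dimensioned to the generated dataset: rotation per
    (slice, phase), strain (%) and segment velocities per
    (slice, 6-segment, phase); onset/peak times of circumferential
    shortening per 6-segment.
    """

    rotation_deg: np.ndarray              # (n_sl, n_ph)
    circ_strain_pct: np.ndarray           # (n_sl, 6, n_ph)
    radial_strain_pct: np.ndarray         # (n_sl, 6, n_ph)
    segment_v_l: np.ndarray               # (n_sl, 6, n_ph) cm/s
    segment_v_r: np.ndarray               # (n_sl, 6, n_ph) cm/s, inward positive
    segment_v_c: np.ndarray               # (n_sl, 6, n_ph) cm/s, clockwise positive
    delays_ms: np.ndarray                 # (6,)
    config: PhantomConfig = None

    def onset_times_ms(self, fraction: float = 0.1) -> np.ndarray:
        """True onset of circumferential shortening per 6-segment (ms)."""
        wave = self.config.waveform()
        return self.delays_ms + wave.onset_time_ms(fraction)

    def peak_times_ms(self) -> np.ndarray:
        """True time of peak circumferential shortening per 6-segment (ms)."""
        return self.delays_ms + self.config.waveform().t_sys_ms


def _area_weighted_u_mean(re, rp):
    """Area-weighted mean of the transmural coordinate u over the annulus."""
    w = rp - re
    num = (rp**3 - re**3) / 3.0 - re * (rp**2 - re**2) / 2.0
    den = (rp**2 - re**2) / 2.0
    return num / (w * den)


def _area_weighted_radius(re, rp):
    return (2.0 / 3.0) * (rp**3 - re**3) / (rp**2 - re**2)


def generate_phantom(cfg: PhantomConfig):
    """Generate a :class:`VelocityDataset` and its :class:`PhantomTruth`.

    Voxels whose center lies inside the annulus between the model contours
    are myocardial (no antialiasing); contours are exact circles of the
    model radii; a border frame of static tissue surrounds the heart.
    """
    cfg.validate()
    wave = cfg.waveform()
    n_ph, n_sl, n = cfg.n_phases, cfg.n_slices, cfg.grid_size
    dt = cfg.phase_interval_ms
    times = np.arange(n_ph) * dt

    # centered in-plane voxel coordinates, +x right, +y up
    coords = (np.arange(n) - (n - 1) / 2.0) * cfg.voxel_mm
    x = np.broadcast_to(coords[None, :], (n, n)).copy()
    y = np.broadcast_to(coords[::-1, None], (n, n)).copy()
    r = np.hypot(x, y)
    r_safe = np.where(r > 1e-9, r, 1e-9)
    theta = np.degrees(np.arctan2(x, y)) % 360.0  # clockwise from +y

    seg6 = SegmentModel.standard(6, cfg.angular_origin_deg)
    seg_id = seg6.assign(theta)                   # (n, n)
    tau = np.asarray(cfg.segment_delays_ms, dtype=float)[seg_id]
    scale = np.asarray(cfg.segment_amplitude_scale, dtype=float)[seg_id]

    re0, rp0 = cfg.endo_radius0(), cfg.epi_radius0()
    a_rot = cfg.rotation_amp()                    # deg
    a_long = cfg.long_amp()                       # mm

    vel = np.zeros((3, n_ph, n_sl, n, n))
    myo = np.zeros((n_ph, n_sl, n, n), dtype=bool)
    endo_c = np.zeros((n_ph, n_sl, cfg.n_contour_points, 2))
    epi_c = np.zeros((n_ph, n_sl, cfg.n_contour_points, 2))

    thc = np.deg2rad(np.arange(cfg.n_contour_points) * 360.0 / cfg.n_contour_points)
    circle = np.stack([np.sin(thc), np.cos(thc)], axis=-1)   # clockwise from +y

    rot_truth = np.zeros((n_sl, n_ph))
    circ_truth = np.zeros((n_sl, 6, n_ph))
    rad_truth = np.zeros((n_sl, 6, n_ph))
    seg_vl = np.zeros((n_sl, 6, n_ph))
    seg_vr = np.zeros((n_sl, 6, n_ph))
    seg_vc = np.zeros((n_sl, 6, n_ph))

    delays6 = np.asarray(cfg.segment_delays_ms, dtype=float)
    scales6 = np.asarray(cfg.segment_amplitude_scale, dtype=float)

    for p, t in enumerate(times):
        g_now = wave.g(t)                         # scalar: geometry is undelayed
        t_eff = t - tau                           # (n, n) per delay segment
        g_eff = wave.g(t_eff) * scale
        dg_eff = wave.dg(t_eff) * scale           # 1/ms

        for s in range(n_sl):
            re = re0[s] * (1 - cfg.endo_contraction_frac * g_now)
            rp = rp0[s] * (1 - cfg.epi_contraction_frac * g_now)
            mask = (r >= re) & (r <= rp)
            myo[p, s] = mask

            # material radial velocity: linear transmural interpolation of
            # the endo/epi radius rates, evaluated at the voxel's transmural
            # position within its own (possibly delayed/scaled) segment's
            # annulus so delayed walls carry a self-consistent motion field
            rdot_e = -re0[s] * cfg.endo_contraction_frac * dg_eff   # mm/ms
            rdot_p = -rp0[s] * cfg.epi_contraction_frac * dg_eff
            re_seg = re0[s] * (1 - cfg.endo_contraction_frac * g_eff)
            rp_seg = rp0[s] * (1 - cfg.epi_contraction_frac * g_eff)
            u = np.clip(
                (r - re_seg) / np.maximum(rp_seg - re_seg, 1e-9), 0.0, 1.0
            )
            rdot = rdot_e + u * (rdot_p - rdot_e)

            if cfg.constant_omega_deg_s is not None:
                omega_deg_ms = np.full_like(rdot, cfg.constant_omega_deg_s / 1000.0)
            else:
                omega_deg_ms = a_rot[s] * dg_eff
            vtan = np.deg2rad(omega_deg_ms) * r    # mm/ms, clockwise positive

            vx = (rdot * x / r_safe + vtan * y / r_safe) * MM_PER_MS_TO_CM_PER_S
            vy = (rdot * y / r_safe - vtan * x / r_safe) * MM_PER_MS_TO_CM_PER_S
            vl = a_long[s] * dg_eff * MM_PER_MS_TO_CM_PER_S   # toward apex positive

            vel[0, p, s][mask] = vx[mask]
            vel[1, p, s][mask] = vy[mask]
            vel[2, p, s][mask] = -vl[mask]         # +z points apex -> base

            endo_c[p, s] = re * circle
            epi_c[p, s] = rp * circle

            # ---- closed-form truth ----------------------------------
            g_seg = wave.g(t - delays6) * scales6
            dg_seg = wave.dg(t - delays6) * scales6
            rm0 = (re0[s] + rp0[s]) / 2.0
            drm = (re0[s] * cfg.endo_contraction_frac
                   + rp0[s] * cfg.epi_contraction_frac) / 2.0
            circ_truth[s, :, p] = -g_seg * drm / rm0 * 100.0
            th0 = rp0[s] - re0[s]
            dth = (re0[s] * cfg.endo_contraction_frac
                   - rp0[s] * cfg.epi_contraction_frac)
            rad_truth[s, :, p] = g_seg * dth / th0 * 100.0
            if cfg.constant_omega_deg_s is not None:
                rot_truth[s, p] = cfg.constant_omega_deg_s / 1000.0 * t
            else:
                rot_truth[s, p] = a_rot[s] * g_seg.mean()
            seg_vl[s, :, p] = a_long[s] * dg_seg * MM_PER_MS_TO_CM_PER_S
            ubar = _area_weighted_u_mean(re, rp)
            rdot_e6 = -re0[s] * cfg.endo_contraction_frac * dg_seg
            rdot_p6 = -rp0[s] * cfg.epi_contraction_frac * dg_seg
            seg_vr[s, :, p] = -(rdot_e6 + ubar * (rdot_p6 - rdot_e6)) * MM_PER_MS_TO_CM_PER_S
            if cfg.constant_omega_deg_s is not None:
                om6 = np.full(6, cfg.constant_omega_deg_s / 1000.0)
            else:
                om6 = a_rot[s] * dg_seg
            seg_vc[s, :, p] = np.deg2rad(om6) * _area_weighted_radius(re, rp) * MM_PER_MS_TO_CM_PER_S

    # background plane, applied to the full slice (myocardium AND static)
    if cfg.background_plane is not None:
        plane = np.broadcast_to(
            np.asarray(cfg.background_plane, dtype=float), (3, n_sl, 3)
        )
        for c in range(3):
            for s in range(n_sl):
                a, b, cc = plane[c, s]
                vel[c, :, s, :, :] += a + b * x + cc * y

    # i.i.d. Gaussian velocity noise over the whole image
    if cfg.noise_sd_cm_s > 0:
        rng = np.random.default_rng(cfg.seed)
        vel += rng.normal(0.0, cfg.noise_sd_cm_s, size=vel.shape)

    border = cfg.static_border_vox
    static = np.zeros((n_sl, n, n), dtype=bool)
    static[:, :border, :] = True
    static[:, -border:, :] = True
    static[:, :, :border] = True
    static[:, :, -border:] = True

    meta = AcquisitionMeta(
        voxel_size_mm=(cfg.voxel_mm,) * 3,
        phase_interval_ms=dt,
        n_phases=n_ph,
        n_slices=n_sl,
        venc_cm_s=cfg.venc_cm_s,
        slice_order="apex_to_base",
    )
    ds = VelocityDataset(
        velocities=vel,
        myo_mask=myo,
        static_mask=static,
        endo_contours=endo_c,
        epi_contours=epi_c,
        meta=meta,
    ).validate()

    truth = PhantomTruth(
        rotation_deg=rot_truth,
        circ_strain_pct=circ_truth,
        radial_strain_pct=rad_truth,
        segment_v_l=seg_vl,
        segment_v_r=seg_vr,
        segment_v_c=seg_vc,
        delays_ms=delays6,
        config=cfg,
    )
    return ds, truth


# Presets --------------------------------------------------------------------
# The lateral wall comprises segments 2 (inferolateral) and 3 (anterolateral)
# of the 6-segment model.

def _healthy(**overrides) -> PhantomConfig:
    base = dict(
        noise_sd_cm_s=0.3,
        background_plane=(0.3, 0.004, -0.003),
    )
    base.update(overrides)
    return PhantomConfig(**base)


def _dcm_like(**overrides) -> PhantomConfig:
    base = dict(
        endo_contraction_frac=0.11,
        epi_contraction_frac=0.04,
        rotation_apex_deg=4.0,
        rotation_base_deg=-2.0,
        long_excursion_apex_mm=1.5,
        long_excursion_base_mm=7.5,
        noise_sd_cm_s=0.3,
        background_plane=(0.3, 0.004, -0.003),
    )
    base.update(overrides)
    return PhantomConfig(**base)


def _lbbb_like(**overrides) -> PhantomConfig:
    base = dict(
        endo_contraction_frac=0.154,
        epi_contraction_frac=0.056,
        rotation_apex_deg=4.0,       # co-rotating apex and base: twist lost
        rotation_base_deg=3.0,
        long_excursion_apex_mm=2.1,
        long_excursion_base_mm=10.5,
        segment_delays_ms=(0.0, 0.0, 150.0, 150.0, 0.0, 0.0),
        segment_amplitude_scale=(1.0, 1.0, 0.6, 0.6, 1.0, 1.0),
        noise_sd_cm_s=0.3,
        background_plane=(0.3, 0.004, -0.003),
    )
    base.update(overrides)
    return PhantomConfig(**base)


PRESETS = {
    "healthy": _healthy,
    "dcm_like": _dcm_like,
    "lbbb_like": _lbbb_like,
}


def make_preset(name: str, **overrides) -> PhantomConfig:
    """Named phantom configurations.

    ``healthy``: full twist, base > apex longitudinal gradient, synchronous.
    ``dcm_like``: globally hypokinetic (amplitudes halved), no delays.
    ``lbbb_like``: reduced amplitudes, a hypocontractile lateral wall
    delayed by 150 ms, and co-rotating (untwisted) apex and base.
    Keyword overrides replace individual config fields (e.g. smaller grids
    for quick experiments).
    """
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return factory(**overrides)
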