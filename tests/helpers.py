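"""Shared builders for synthetic curve sets and velocity fields."""

import numpy as np

from tpm3d.datamodel import AcquisitionMeta, CurveSet, LocalVelocityField
from tpm3d.preprocess import interp_grid, spline_resample


def curveset_from_segments(times, seg, direction="l", factor=8):
    """CurveSet with given per-segment curves; slice curves are segment means.

    ``seg`` is (n_sl, n_seg, n_t).
    """
    cs = CurveSet(time_ms=np.asarray(times, float),
                  time_interp_ms=interp_grid(np.asarray(times, float), factor))
    sl = seg.mean(axis=1)
    cs.slice_velocity[direction] = sl
    _, cs.slice_velocity_interp[direction] = spline_resample(times, sl, factor)
    key = (direction, seg.shape[1])
    cs.segment_velocity[key] = seg
    _, cs.segment_velocity_interp[key] = spline_resample(times, seg, factor)
    return cs


def ring_field(omegas_deg_s, radius_range_mm=(28.0, 32.0), voxel_mm=2.0,
               grid=48, n_phases=8, dt_ms=40.0, slice_gap_mm=60.0):
    """Rigidly rotating annulus LocalVelocityField, one omega per slice.

    v_c = omega * r exactly (cm/s, clockwise positive); v_r = v_l = 0.
    """
    omegas = np.asarray(omegas_deg_s, float)
    n_sl = len(omegas)
    coords = (np.arange(grid) - (grid - 1) / 2.0) * voxel_mm
    x = np.broadcast_to(coords[None, :], (grid, grid))
    y = np.broadcast_to(coords[::-1, None], (grid, grid))
    r = np.hypot(x, y)
    theta = np.degrees(np.arctan2(x, y)) % 360.0
    ring = (r >= radius_range_mm[0]) & (r <= radius_range_mm[1])

    mask = np.broadcast_to(ring, (n_phases, n_sl, grid, grid)).copy()
    radius = np.broadcast_to(r, (n_phases, n_sl, grid, grid)).copy()
    th = np.broadcast_to(theta, (n_phases, n_sl, grid, grid)).copy()
    v_c = np.zeros((n_phases, n_sl, grid, grid))
    for s, om in enumerate(omegas):
        v_c[:, s] = np.where(ring, np.deg2rad(om) * r / 10.0, 0.0)
    zeros = np.zeros_like(v_c)
    meta = AcquisitionMeta(
        voxel_size_mm=(voxel_mm, voxel_mm, slice_gap_mm),
        phase_interval_ms=dt_ms,
        n_phases=n_phases,
        n_slices=n_sl,
    )
    return LocalVelocityField(
        v_l=zeros.copy(), v_r=zeros.copy(), v_c=v_c,
        mask=mask, centers_mm=np.zeros((n_phases, n_sl, 2)),
        theta_deg=th, radius_mm=radius, meta=meta,
    )
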