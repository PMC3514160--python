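"""Curve families derived from the local velocity field: velocity-time,
torsion-rate-time, rotation-angle-time and strain-time curves.

Displacements are obtained by explicit forward (Euler) integration of
segment-averaged velocities,

    x_t = x_0 + dt * (v_0 + v_1 + ... + v_{t-1}),

i.e. each tracked point advances per phase interval by the mean in-plane
velocity of the angular bin it currently occupies.  Tracking is purely
in-plane (2D within the short-axis slice); the longitudinal velocity only
feeds the velocity-time parameters.
"""

from __future__ import annotations

import numpy as np

from .datamodel import (
    CurveSet,
    LocalVelocityField,
    SegmentModel,
    TrackedPoints,
    ValidationError,
)
from .preprocess import spline_resample, interp_grid

__all__ = [
    "extract_vt_curves",
    "track_displacement",
    "rotation_angle_curve",
    "torsion_rate_curve",
    "strain_curves",
    "contour_radius_at",
]

CM_S_TO_MM_MS = 0.01

#: angular bins used to look up tracking velocities; finer than any strain
#: segment model so that chord endpoints of one segment sample distinct bins
N_OCCUPANCY_BINS = 24

#: chord seed points sit this fraction of the segment span inside each
#: boundary, so their bin occupancy is unambiguous at phase 0
CHORD_INSET_FRACTION = 0.05


# -- velocity-time curves -----------------------------------------------------

def _segment_means(values: np.ndarray, ids: np.ndarray, n_seg: int):
    """Per-phase, per-slice segment means via bincount.

    ``values`` and ``ids`` are (n_ph, n_sl, ny, nx); ids are -1 outside the
    mask.  Returns (means (n_sl, n_seg, n_ph), counts) with NaN where a
    segment has no voxels.
    """
    n_ph, n_sl = values.shape[:2]
    means = np.full((n_sl, n_seg, n_ph), np.nan)
    counts = np.zeros((n_sl, n_seg, n_ph), dtype=int)
    for p in range(n_ph):
        for s in range(n_sl):
            sel = ids[p, s] >= 0
            if not sel.any():
                continue
            i = ids[p, s][sel]
            v = values[p, s][sel]
            cnt = np.bincount(i, minlength=n_seg)
            tot = np.bincount(i, weights=v, minlength=n_seg)
            counts[s, :, p] = cnt
            with np.errstate(invalid="ignore"):
                means[s, :, p] = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
    return means, counts


def _impute_missing(curves: np.ndarray, times: np.ndarray) -> int:
    """Fill NaN samples of (..., n_t) curves by interpolation over neighbors."""
    flat = curves.reshape(-1, curves.shape[-1])
    n_filled = 0
    for row in flat:
        bad = ~np.isfinite(row)
        if bad.any() and (~bad).sum() >= 2:
            row[bad] = np.interp(times[bad], times[~bad], row[~bad])
            n_filled += int(bad.sum())
    return n_filled


def extract_vt_curves(
    field: LocalVelocityField,
    seg_counts=(6, 24),
    factor: int = 8,
) -> CurveSet:
    """Slice-mean and segment-mean velocity-time curves, spline-interpolated.

    Velocities are averaged unweighted over the myocardial voxels of the
    slice (or of the segment) at each phase; missing samples of an empty
    segment are imputed by interpolation over neighbouring phases and
    counted in the provenance record.
    """
    times = field.meta.trigger_time_ms
    curves = CurveSet(time_ms=times, time_interp_ms=interp_grid(times, factor))
    n_imputed = 0
    for d in ("l", "r", "c"):
        v = field.component(d)
        n_ph, n_sl = v.shape[:2]
        slice_means = np.zeros((n_sl, n_ph))
        for p in range(n_ph):
            for s in range(n_sl):
                m = field.mask[p, s]
                slice_means[s, p] = v[p, s][m].mean() if m.any() else np.nan
        n_imputed += _impute_missing(slice_means, times)
        curves.slice_velocity[d] = slice_means
        _, curves.slice_velocity_interp[d] = spline_resample(times, slice_means, factor)
        for n_seg in seg_counts:
            ids = field.segment_ids[n_seg]
            means, _ = _segment_means(v, ids, n_seg)
            n_imputed += _impute_missing(means, times)
            curves.segment_velocity[(d, n_seg)] = means
            _, curves.segment_velocity_interp[(d, n_seg)] = spline_resample(
                times, means, factor
            )
    curves.provenance["spline"] = {"method": "natural_cubic_spline", "factor": factor}
    curves.provenance["imputed_samples"] = n_imputed
    return curves


# -- forward tracking ---------------------------------------------------------

def contour_radius_at(contour: np.ndarray, center: np.ndarray, theta_deg):
    """Radius of a closed contour about ``center`` at the given angles.

    The contour's points are converted to polar form and the radius is
    interpolated periodically in angle.
    """
    d = contour - center[None, :]
    th = np.degrees(np.arctan2(d[:, 0], d[:, 1])) % 360.0
    r = np.hypot(d[:, 0], d[:, 1])
    order = np.argsort(th)
    th_s, r_s = th[order], r[order]
    th_ext = np.concatenate([th_s - 360.0, th_s, th_s + 360.0])
    r_ext = np.concatenate([r_s, r_s, r_s])
    return np.interp(np.mod(theta_deg, 360.0), th_ext, r_ext)


def _polar_linear_fits(field: LocalVelocityField, occ: SegmentModel):
    """Per (phase, slice, occupancy bin) transmural velocity model.

    Within each angular bin the inward-radial and circumferential velocity
    components are fitted as linear functions of the radius,
    ``v ~ a + b (r - r_bar)``, by least squares over the bin's myocardial
    voxels.  Evaluated at a tracked point's own angle and radius this
    reduces to the bin-average velocity at the bin centroid while carrying
    the local direction and the transmural gradient, which a single mean
    vector per bin cannot (the gradient is what radial strain measures).

    Returns ``coef`` (n_ph, n_sl, n_bins, 5) holding
    (a_r, b_r, a_c, b_c, r_bar).  Bins with < 2 voxels or no radial spread
    fall back to the bin (or slice) mean with zero gradient.
    """
    ids = occ.assign(field.theta_deg)
    ids = np.where(field.mask, ids, -1)
    n_ph, n_sl = field.mask.shape[:2]
    n_bins = occ.n_seg
    coef = np.zeros((n_ph, n_sl, n_bins, 5))
    for p in range(n_ph):
        for s in range(n_sl):
            m = field.mask[p, s]
            slice_mean = (
                np.array([field.v_r[p, s][m].mean(), field.v_c[p, s][m].mean()])
                if m.any()
                else np.zeros(2)
            )
            for k in range(n_bins):
                sel = ids[p, s] == k
                n = int(sel.sum())
                if n == 0:
                    coef[p, s, k] = (slice_mean[0], 0.0, slice_mean[1], 0.0, 0.0)
                    continue
                rr = field.radius_mm[p, s][sel]
                vr = field.v_r[p, s][sel]
                vc = field.v_c[p, s][sel]
                rbar = rr.mean()
                if n < 2 or np.ptp(rr) < 1e-9:
                    coef[p, s, k] = (vr.mean(), 0.0, vc.mean(), 0.0, rbar)
                    continue
                design = np.column_stack([np.ones(n), rr - rbar])
                sol, *_ = np.linalg.lstsq(
                    design, np.column_stack([vr, vc]), rcond=None
                )
                coef[p, s, k] = (sol[0, 0], sol[1, 0], sol[0, 1], sol[1, 1], rbar)
    return coef


def _eval_polar_velocity(coef_psl, bins, theta_deg, radius_mm):
    """In-plane (vx, vy) in cm/s from the transmural fits of one phase/slice.

    ``coef_psl`` is (n_sl, n_bins, 5); ``bins``, ``theta_deg`` and
    ``radius_mm`` are (n_sl, n_pts) for the tracked points.
    """
    n_sl = coef_psl.shape[0]
    c = coef_psl[np.arange(n_sl)[:, None], bins]        # (n_sl, n_pts, 5)
    dr = radius_mm - c[..., 4]
    v_r = c[..., 0] + c[..., 1] * dr                    # inward positive
    v_c = c[..., 2] + c[..., 3] * dr                    # clockwise positive
    th = np.deg2rad(theta_deg)
    sin, cos = np.sin(th), np.cos(th)
    vx = -v_r * sin + v_c * cos
    vy = -v_r * cos - v_c * sin
    return np.stack([vx, vy], axis=-1)


def track_displacement(field: LocalVelocityField, model: SegmentModel) -> TrackedPoints:
    """Forward-track the material points of one segment model.

    Seeds at phase 0, per (slice, segment): the centerline point at the
    segment-center angle, two centerline chord points just inside the
    segment's angular boundaries, and an endo/epi pair on the radial
    normal through the segment center.  Per phase interval every point
    advances (explicit forward Euler, the velocity-summation displacement
    rule) by the segment-averaged velocity of the fine angular occupancy
    bin it currently occupies, evaluated at the point through the bin's
    transmural linear velocity model (see :func:`_polar_linear_fits`).
    Points leaving the image grid are frozen and flagged.
    """
    meta = field.meta
    n_ph, n_sl = field.mask.shape[:2]
    n_seg = model.n_seg
    dt = meta.phase_interval_ms
    occ = SegmentModel.standard(N_OCCUPANCY_BINS, model.angular_origin_deg)
    coef = _polar_linear_fits(field, occ)

    ny, nx = field.mask.shape[-2:]
    dxv, dyv = meta.voxel_size_mm[0], meta.voxel_size_mm[1]
    half_x = nx * dxv / 2.0
    half_y = ny * dyv / 2.0

    width = 360.0 / n_seg
    th_center = model.centers_deg()
    th_a = th_center - width / 2.0 + CHORD_INSET_FRACTION * width
    th_b = th_center + width / 2.0 - CHORD_INSET_FRACTION * width

    shape = (n_sl, n_seg, n_ph, 2)
    pts = {name: np.zeros(shape) for name in ("center", "chord_a", "chord_b", "endo", "epi")}
    truncated = np.zeros((n_sl, n_seg), dtype=bool)

    # seed on the phase-0 centerline / contours
    # (field has no contours; radius via mask-free polar geometry is not
    #  available, so seeds are passed through the phantom/pipeline contours
    #  stored on the field if present, else mask radii)
    for s in range(n_sl):
        c0 = field.centers_mm[0, s]
        if getattr(field, "endo_contours", None) is not None:
            r_endo = contour_radius_at(field.endo_contours[0, s], c0, th_center)
            r_epi = contour_radius_at(field.epi_contours[0, s], c0, th_center)
            r_endo_a = contour_radius_at(field.endo_contours[0, s], c0, th_a)
            r_epi_a = contour_radius_at(field.epi_contours[0, s], c0, th_a)
            r_endo_b = contour_radius_at(field.endo_contours[0, s], c0, th_b)
            r_epi_b = contour_radius_at(field.epi_contours[0, s], c0, th_b)
        else:
            m = field.mask[0, s]
            rr = field.radius_mm[0, s][m]
            r_in, r_out = rr.min(), rr.max()
            r_endo = r_endo_a = r_endo_b = np.full(n_seg, r_in)
            r_epi = r_epi_a = r_epi_b = np.full(n_seg, r_out)
        r_mid = (r_endo + r_epi) / 2.0
        r_mid_a = (r_endo_a + r_epi_a) / 2.0
        r_mid_b = (r_endo_b + r_epi_b) / 2.0

        def polar(radius, theta):
            th = np.deg2rad(theta)
            return c0 + np.stack([radius * np.sin(th), radius * np.cos(th)], axis=-1)

        pts["center"][s, :, 0] = polar(r_mid, th_center)
        pts["chord_a"][s, :, 0] = polar(r_mid_a, th_a)
        pts["chord_b"][s, :, 0] = polar(r_mid_b, th_b)
        pts["endo"][s, :, 0] = polar(r_endo, th_center)
        pts["epi"][s, :, 0] = polar(r_epi, th_center)

    # forward Euler through the cycle
    for p in range(n_ph - 1):
        centers_p = field.centers_mm[p]                       # (n_sl, 2)
        for name in pts:
            pos = pts[name][:, :, p, :]                       # (n_sl, n_seg, 2)
            d = pos - centers_p[:, None, :]
            th = np.degrees(np.arctan2(d[..., 0], d[..., 1])) % 360.0
            rad = np.hypot(d[..., 0], d[..., 1])
            bins = occ.assign(th)
            v = _eval_polar_velocity(coef[p], bins, th, rad)  # cm/s
            new = pos + v * CM_S_TO_MM_MS * dt
            out = (np.abs(new[..., 0]) > half_x) | (np.abs(new[..., 1]) > half_y)
            truncated |= out
            pts[name][:, :, p + 1, :] = np.where(out[..., None], pos, new)

    return TrackedPoints(
        center=pts["center"],
        chord_a=pts["chord_a"],
        chord_b=pts["chord_b"],
        endo=pts["endo"],
        epi=pts["epi"],
        model=model,
        truncated=truncated,
        provenance={
            "integration": "forward_euler",
            "dt_ms": dt,
            "occupancy_bins": occ.n_seg,
            "chord_inset_fraction": CHORD_INSET_FRACTION,
            "n_truncated": int(truncated.sum()),
        },
    )


# -- rotation angle -----------------------------------------------------------

def rotation_angle_curve(
    tracked: TrackedPoints,
    field: LocalVelocityField,
    min_radius_voxels: float = 0.5,
):
    """Per-slice rotation angle relative to phase 0, clockwise positive.

    Each tracked segment-center point contributes the unwrapped change of
    its polar angle about the current blood-pool center; the slice curve is
    the mean over segments.  Segments whose point approaches the center
    closer than half a voxel are excluded.  Returns (alpha (n_sl, n_ph),
    n_excluded).
    """
    n_sl, n_seg, n_ph, _ = tracked.center.shape
    centers = np.moveaxis(field.centers_mm, 0, 1)           # (n_sl, n_ph, 2)
    d = tracked.center - centers[:, None, :, :]
    radius = np.hypot(d[..., 0], d[..., 1])
    theta = np.arctan2(d[..., 0], d[..., 1])                # rad, clockwise from +y
    theta = np.unwrap(theta, axis=-1)
    delta = np.degrees(theta - theta[..., :1])

    min_r = min_radius_voxels * field.meta.voxel_size_mm[0]
    ok = (radius > min_r).all(axis=-1)                      # (n_sl, n_seg)
    n_excl = int((~ok).sum())
    alpha = np.zeros((n_sl, n_ph))
    for s in range(n_sl):
        if ok[s].any():
            alpha[s] = delta[s, ok[s]].mean(axis=0)
    return alpha, n_excl


# -- torsion rate -------------------------------------------------------------

def torsion_rate_curve(
    field: LocalVelocityField,
    apex_slice: int = 0,
    base_slice: int = -1,
    min_radius_voxels: float = 0.5,
):
    """Global torsion-rate-time curve in deg/(cm s).

    T(t) = (omega_apex - omega_base) * (r_apex + r_base) / (2 d) where
    omega is the slice-mean angular velocity obtained voxel-wise as
    v_c / r (exact for rigid rotation), r the time-averaged mean
    myocardial radius of the slice, and d the apex-base distance of the
    two analysed slices (the most apical and most basal by default).
    """
    n_ph, n_sl = field.mask.shape[:2]
    apex = apex_slice % n_sl
    base = base_slice % n_sl
    dz_mm = abs(base - apex) * field.meta.voxel_size_mm[2]
    if dz_mm <= 0:
        raise ValidationError("torsion rate needs two distinct slices")
    min_r = min_radius_voxels * field.meta.voxel_size_mm[0]

    def slice_omega_and_radius(s):
        om = np.zeros(n_ph)
        radii = np.zeros(n_ph)
        for p in range(n_ph):
            m = field.mask[p, s] & (field.radius_mm[p, s] > min_r)
            r = field.radius_mm[p, s][m]
            vc = field.v_c[p, s][m]
            om[p] = np.degrees(10.0 * vc / r).mean() if m.any() else 0.0
            radii[p] = r.mean() if m.any() else np.nan
        return om, np.nanmean(radii) / 10.0     # deg/s, cm

    om_a, r_a = slice_omega_and_radius(apex)
    om_b, r_b = slice_omega_and_radius(base)
    torsion = (om_a - om_b) * (r_a + r_b) / (2.0 * dz_mm / 10.0)
    return torsion


# -- strain -------------------------------------------------------------------

def strain_curves(tracked: TrackedPoints, min_chord_mm: float = 0.1):
    """Cumulative circumferential and radial strain (%) per (slice, segment).

    Circumferential strain of a segment is the relative length change of
    the chord between its tracked bounding centerline points; radial
    strain is the relative change of the tracked endo-epi pair distance.
    Both are referenced to phase 0.  Degenerate chords (< ``min_chord_mm``)
    are flagged NaN.
    """
    chord = np.linalg.norm(tracked.chord_a - tracked.chord_b, axis=-1)
    wall = np.linalg.norm(tracked.endo - tracked.epi, axis=-1)

    def rel(lengths):
        l0 = lengths[..., :1]
        ok = l0 >= min_chord_mm
        with np.errstate(invalid="ignore", divide="ignore"):
            s = (lengths - l0) / l0 * 100.0
        return np.where(ok, s, np.nan)

    return {"circumferential": rel(chord), "radial": rel(wall)}
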