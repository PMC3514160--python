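"""Background phase correction, local-direction decomposition, segment
assignment and cubic-spline temporal interpolation."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .datamodel import (
    LocalVelocityField,
    SegmentModel,
    ValidationError,
    VelocityDataset,
)

__all__ = [
    "correct_background_phase",
    "decompose_local",
    "assign_segments",
    "interpolate_curve",
    "interp_grid",
    "InterpolatedCurve",
]

log = logging.getLogger(__name__)


# -- background phase correction --------------------------------------------

def correct_background_phase(ds: VelocityDataset, min_static_voxels: int = 10):
    """Remove the linear background phase offset from every slice.

    For each velocity component, phase and slice independently, a plane
    ``a + b*x + c*y`` is least-squares fitted to the static-tissue voxels
    (slice-local mm coordinates centered on the image center, which keeps
    the offset and slope estimates decorrelated) and subtracted from the
    whole slice.  If the static voxels of a slice are (near-)collinear the
    fit falls back to a constant offset with a warning.

    Returns a corrected copy; the fitted coefficients are attached as
    ``.background_coefficients`` with shape (3, n_phases, n_slices, 3)
    ordered (a, b, c).
    """
    nc, n_ph, n_sl, ny, nx = ds.velocities.shape
    x_mm, y_mm = ds.inplane_coords_mm()
    out = ds.copy()
    coeffs = np.zeros((3, n_ph, n_sl, 3))

    for s in range(n_sl):
        sel = ds.static_mask[s]
        n_stat = int(sel.sum())
        if n_stat < min_static_voxels:
            raise ValidationError(
                f"slice {s}: only {n_stat} static voxels (need >= {min_static_voxels})"
            )
        xs, ys = x_mm[sel], y_mm[sel]
        design = np.column_stack([np.ones_like(xs), xs, ys])
        # collinearity check via the rank of the centered coordinates
        scale = max(1.0, float(np.ptp(xs) + np.ptp(ys)))
        degenerate = np.linalg.matrix_rank(design, tol=1e-8 * scale) < 3
        if degenerate:
            warnings.warn(
                f"slice {s}: static voxels are collinear; "
                "falling back to constant-offset background correction",
                stacklevel=2,
            )
        b = ds.velocities[:, :, s][:, :, sel]          # (3, n_ph, n_stat)
        b2 = b.reshape(-1, n_stat).T                   # (n_stat, 3*n_ph)
        if degenerate:
            sol = np.zeros((3, b2.shape[1]))
            sol[0] = b2.mean(axis=0)
        else:
            sol, *_ = np.linalg.lstsq(design, b2, rcond=None)
        sol = sol.T.reshape(3, n_ph, 3)                # (comp, phase, (a,b,c))
        coeffs[:, :, s, :] = sol
        plane = (
            sol[:, :, 0, None, None]
            + sol[:, :, 1, None, None] * x_mm[None, None]
            + sol[:, :, 2, None, None] * y_mm[None, None]
        )
        out.velocities[:, :, s] -= plane

    out.background_coefficients = coeffs
    log.debug("background plane coefficients: mean |a|=%.3g, |b|=%.3g, |c|=%.3g",
              *np.abs(coeffs).mean(axis=(1, 2))[0])
    return out


# -- local direction decomposition -------------------------------------------

def decompose_local(ds: VelocityDataset) -> LocalVelocityField:
    """Resolve (vx, vy, vz) into longitudinal/radial/circumferential parts.

    Per (phase, slice) the blood-pool center is the centroid of the
    endocardial contour (myocardial-mask centroid if the contour is
    degenerate).  The radial direction points from the voxel toward the
    center (inward motion positive, matching the positive systolic lobes
    of the radial curves), the circumferential direction is 90 degrees
    clockwise from outward-radial in the viewing orientation (clockwise
    motion positive), and the longitudinal component is the through-plane
    velocity signed toward the apex.
    """
    nc, n_ph, n_sl, ny, nx = ds.velocities.shape
    x_mm, y_mm = ds.inplane_coords_mm()

    centers = np.zeros((n_ph, n_sl, 2))
    for p in range(n_ph):
        for s in range(n_sl):
            c = ds.endo_contours[p, s]
            if c.shape[0] >= 3 and np.isfinite(c).all():
                centers[p, s] = c.mean(axis=0)
            else:
                m = ds.myo_mask[p, s]
                if not m.any():
                    raise ValidationError(
                        f"no contour and empty myocardial mask at phase {p}, slice {s}"
                    )
                centers[p, s] = (x_mm[m].mean(), y_mm[m].mean())

    dx = x_mm[None, None] - centers[:, :, 0, None, None]
    dy = y_mm[None, None] - centers[:, :, 1, None, None]
    r = np.hypot(dx, dy)
    r_safe = np.where(r > 1e-9, r, 1e-9)
    theta = np.degrees(np.arctan2(dx, dy)) % 360.0     # clockwise from +y

    vx, vy, vz = ds.velocities
    mask = ds.myo_mask
    v_l = np.where(mask, -vz, 0.0)
    v_r = np.where(mask, -(vx * dx + vy * dy) / r_safe, 0.0)
    v_c = np.where(mask, (vx * dy - vy * dx) / r_safe, 0.0)

    return LocalVelocityField(
        v_l=v_l,
        v_r=v_r,
        v_c=v_c,
        mask=mask,
        centers_mm=centers,
        theta_deg=theta,
        radius_mm=r,
        meta=ds.meta,
        endo_contours=ds.endo_contours,
        epi_contours=ds.epi_contours,
    )


def assign_segments(field: LocalVelocityField, model: SegmentModel) -> LocalVelocityField:
    """Attach per-voxel segment ids for one segment model (in place).

    Assignment is Eulerian: the angular bin of each voxel is recomputed at
    every phase about that phase's blood-pool center.  Voxels outside the
    myocardial mask get id -1.
    """
    ids = model.assign(field.theta_deg).astype(np.int16)
    ids[~field.mask] = -1
    field.segment_ids[model.n_seg] = ids
    field.segment_models[model.n_seg] = model
    return field


# -- temporal interpolation ---------------------------------------------------

@dataclass
class InterpolatedCurve:
    """A cubic-spline resampled time curve.

    The spline (natural boundary conditions) passes exactly through the
    measured samples; the grid covers [first, last] trigger time at
    ``factor`` times the sample density.
    """

    time_ms: np.ndarray
    values: np.ndarray
    sample_time_ms: np.ndarray
    sample_values: np.ndarray
    tag: str = ""
    scope: str = ""
    record: dict = field(default_factory=dict)


def interp_grid(sample_times: np.ndarray, factor: int) -> np.ndarray:
    """Uniform grid at ``factor`` times the sample density (endpoints kept)."""
    n = len(sample_times)
    return np.linspace(sample_times[0], sample_times[-1], (n - 1) * factor + 1)


def spline_resample(sample_times, values, factor: int, axis: int = -1):
    """Natural cubic spline through the samples, evaluated on the fine grid."""
    sample_times = np.asarray(sample_times, dtype=float)
    if len(sample_times) < 4:
        raise ValidationError("cubic-spline interpolation needs >= 4 samples")
    if np.any(np.diff(sample_times) <= 0):
        raise ValidationError("sample times must be strictly increasing")
    grid = interp_grid(sample_times, int(factor))
    cs = CubicSpline(sample_times, values, axis=axis, bc_type="natural")
    return grid, cs(grid)


def interpolate_curve(
    sample_times,
    sample_values,
    factor: int = 8,
    tag: str = "",
    scope: str = "",
) -> InterpolatedCurve:
    """Cubic-spline upsample a time-value curve (natural boundary conditions)."""
    if factor < 1:
        raise ValidationError("upsampling factor must be >= 1")
    sample_values = np.asarray(sample_values, dtype=float)
    grid, vals = spline_resample(sample_times, sample_values, factor)
    return InterpolatedCurve(
        time_ms=grid,
        values=vals,
        sample_time_ms=np.asarray(sample_times, dtype=float),
        sample_values=sample_values,
        tag=tag,
        scope=scope,
        record={"method": "natural_cubic_spline", "factor": int(factor)},
    )
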