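"""Scalar parameters from torsion-rate, rotation-angle and strain-time
curves: peak torsion rates, base-apex rotation correlation (BARC),
temporal uniformity of strain (TUS; circumferential = CURE), regional
strain variance (RVS) and its root (RVVPS), onset/peak-of-shortening
statistics and delay vectors, coefficient of variation (CV) and the
septal-lateral peak-strain difference."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import CurveSet, SegmentModel, ValidationError
from .velocity_params import CycleWindows, fourier_uniformity, pearson

__all__ = [
    "torsion_peaks",
    "detect_rest_phase",
    "barc",
    "tus",
    "rvs",
    "rvvps",
    "OnsetPeakTable",
    "onset_peak_times",
    "DelayVector",
    "delay_vectors",
    "cv",
    "diff_sl_peak_cs",
]


def torsion_peaks(time: np.ndarray, torsion: np.ndarray, windows: CycleWindows):
    """(peak systolic, peak diastolic) torsion rate in deg/(cm s)."""
    sel_s = windows.systolic(time)
    sel_d = windows.diastolic(time)
    return float(np.max(torsion[sel_s])), float(np.min(torsion[sel_d]))


def detect_rest_phase(
    curves: CurveSet,
    windows: CycleWindows,
    fraction: float = 0.1,
    min_consecutive: int = 2,
) -> float:
    """Start time of the diastolic resting phase (diastasis), in ms.

    First time after the global diastolic longitudinal velocity peak at
    which the global speed |v| = sqrt(v_l^2 + v_r^2 + v_c^2) (of the
    global-mean curves) stays below ``fraction`` of its cycle maximum for
    at least ``min_consecutive`` consecutive interpolated samples.  Falls
    back to the end of the cycle if no such interval exists.
    """
    t = curves.time_interp_ms
    g = {d: curves.slice_velocity_interp[d].mean(axis=0) for d in ("l", "r", "c")}
    speed = np.sqrt(g["l"] ** 2 + g["r"] ** 2 + g["c"] ** 2)
    vmax = speed.max()
    if vmax == 0.0:
        return float(t[-1])
    dia = windows.diastolic(t)
    gl = np.where(dia, g["l"], np.inf)
    i_dia_peak = int(np.argmin(gl))
    low = speed < fraction * vmax
    run = 0
    for i in range(i_dia_peak, len(t)):
        run = run + 1 if low[i] else 0
        if run >= min_consecutive:
            return float(t[i - min_consecutive + 1])
    return float(t[-1])


def barc(
    alpha_apex: np.ndarray,
    alpha_base: np.ndarray,
    time: np.ndarray,
    t_rest: float,
):
    """Base-apex rotation correlation over [0, t_rest].

    Pearson correlation between the most-apical and most-basal slice
    rotation-angle curves, evaluated up to the start of the diastolic
    resting phase.  Negative values indicate counter-rotation (normal
    twist); co-rotation yields positive values.  Returns None (undefined)
    when either curve has zero variance on the window.
    """
    sel = time <= t_rest
    if sel.sum() < 3:
        sel = np.ones_like(time, dtype=bool)
    r = pearson(alpha_apex[sel], alpha_base[sel])
    return None if np.isnan(r) else float(r)


def tus(curves: CurveSet, component: str, n_seg: int = 24) -> float:
    """Temporal uniformity of strain (circumferential instance = CURE).

    Identical spatial-Fourier machinery as the velocity uniformity, applied
    to the per-segment strain profiles.
    """
    profiles = curves.strain_interp[(component, n_seg)]
    value, _ = fourier_uniformity(np.nan_to_num(profiles, nan=0.0))
    return value


def rvs(strain: np.ndarray):
    """Regional variance of strain over all (slice, segment) at each time.

    ``strain`` is (n_sl, n_seg, n_t) in %; returns (curve in %^2, max).
    Sample (n-1) variance; NaN segments are excluded per time point.
    """
    n_t = strain.shape[-1]
    flat = strain.reshape(-1, n_t)
    with np.errstate(invalid="ignore"):
        curve = np.nanvar(flat, axis=0, ddof=1)
    curve = np.nan_to_num(curve, nan=0.0)
    return curve, float(curve.max())


def rvvps(strain: np.ndarray):
    """Regional standard deviation of strain (square root of RVS), in %."""
    curve, _ = rvs(strain)
    curve = np.sqrt(curve)
    return curve, float(curve.max())


@dataclass
class OnsetPeakTable:
    """Onset and peak times of circumferential shortening per (slice, segment).

    ``t_onset`` is the first time a segment's strain falls below
    ``onset_fraction`` of its own (negative) peak; ``t_peak`` the time of
    the most negative strain.  Segments that never shorten are NaN.
    """

    t_onset: np.ndarray        # (n_sl, n_seg) ms
    t_peak: np.ndarray         # (n_sl, n_seg) ms
    peak_strain: np.ndarray    # (n_sl, n_seg) %
    onset_fraction: float
    n_excluded: int = 0
    record: dict = field(default_factory=dict)


def onset_peak_times(
    strain: np.ndarray,
    time: np.ndarray,
    onset_fraction: float = 0.1,
    min_peak_pct: float = 1e-6,
) -> OnsetPeakTable:
    """Detect shortening onset/peak times on interpolated strain curves.

    ``strain`` is (n_sl, n_seg, n_t) circumferential strain in %
    (shortening negative).  Segments whose strain never falls below
    ``-min_peak_pct`` are excluded (NaN).
    """
    n_sl, n_seg, n_t = strain.shape
    t_on = np.full((n_sl, n_seg), np.nan)
    t_pk = np.full((n_sl, n_seg), np.nan)
    pk = np.full((n_sl, n_seg), np.nan)
    n_excl = 0
    for s in range(n_sl):
        for k in range(n_seg):
            curve = strain[s, k]
            if not np.isfinite(curve).all() or curve.min() >= -min_peak_pct:
                n_excl += 1
                continue
            i_pk = int(np.argmin(curve))
            t_pk[s, k] = time[i_pk]
            pk[s, k] = curve[i_pk]
            thresh = onset_fraction * curve[i_pk]       # negative
            below = np.where(curve <= thresh)[0]
            t_on[s, k] = time[below[0]]
    return OnsetPeakTable(
        t_onset=t_on,
        t_peak=t_pk,
        peak_strain=pk,
        onset_fraction=onset_fraction,
        n_excluded=n_excl,
    )


def sd_times(table: OnsetPeakTable, kind: str):
    """Pooled sample SD (ms) of onset or peak times over all segments/slices."""
    tt = {"onset": table.t_onset, "peak": table.t_peak}[kind]
    v = tt[np.isfinite(tt)]
    if v.size < 2:
        return None
    return float(np.std(v, ddof=1))


@dataclass
class DelayVector:
    """Septal-lateral, inferior-anterior and apical-basal time delays (ms)."""

    sl: float
    ia: float
    ab: float
    kind: str = "onset"   # or "peak"


def _wall_mean(values_row: np.ndarray, model: SegmentModel, wall: str):
    idx = model.segments_of_wall(wall)
    v = values_row[idx]
    v = v[np.isfinite(v)]
    return v.mean() if v.size else np.nan


def delay_vectors(table: OnsetPeakTable, model: SegmentModel):
    """Onset (OS) and peak (PS) of shortening delay vectors.

    Per slice, SL = mean time over septal segments minus mean over lateral
    segments and IA = inferior minus anterior; both are averaged over the
    slices where the walls are defined.  AB = mean time of the most apical
    slice minus the most basal slice.  Returns (os_vector, ps_vector);
    components with no usable data are NaN.
    """
    out = []
    for kind, tt in (("onset", table.t_onset), ("peak", table.t_peak)):
        comps = {}
        for name, (w1, w2) in {
            "sl": ("septal", "lateral"),
            "ia": ("inferior", "anterior"),
        }.items():
            per_slice = []
            for row in tt:
                a = _wall_mean(row, model, w1)
                b = _wall_mean(row, model, w2)
                if np.isfinite(a) and np.isfinite(b):
                    per_slice.append(a - b)
            comps[name] = float(np.mean(per_slice)) if per_slice else np.nan
        apex, base = tt[0], tt[-1]
        a = apex[np.isfinite(apex)]
        b = base[np.isfinite(base)]
        comps["ab"] = float(a.mean() - b.mean()) if (a.size and b.size and len(tt) > 1) else np.nan
        out.append(DelayVector(sl=comps["sl"], ia=comps["ia"], ab=comps["ab"], kind=kind))
    return tuple(out)


def cv(strain: np.ndarray, time: np.ndarray, scope: str = "global"):
    """Coefficient of variation of segmental strain at maximal contraction.

    The time of maximal contraction is where the mean strain over all
    (slice, segment) is most negative (``global``) or per slice
    (``per_slice``, then averaged).  CV = SD * 100 / |mean| at that time,
    in %.  Undefined (None) if the mean strain magnitude is below 1e-3 %.
    """
    n_t = strain.shape[-1]
    flat = strain.reshape(-1, n_t)
    if scope == "global":
        mean_curve = np.nanmean(flat, axis=0)
        i0 = int(np.nanargmin(mean_curve))
        vals = flat[:, i0]
        vals = vals[np.isfinite(vals)]
        m = vals.mean()
        if abs(m) < 1e-3 or vals.size < 2:
            return None
        return float(np.std(vals, ddof=1) * 100.0 / abs(m))
    if scope == "per_slice":
        res = []
        for sl in strain:
            mean_curve = np.nanmean(sl, axis=0)
            i0 = int(np.nanargmin(mean_curve))
            vals = sl[:, i0]
            vals = vals[np.isfinite(vals)]
            if vals.size >= 2 and abs(vals.mean()) >= 1e-3:
                res.append(np.std(vals, ddof=1) * 100.0 / abs(vals.mean()))
        return float(np.mean(res)) if res else None
    raise ValidationError(f"unknown scope {scope!r}")


def diff_sl_peak_cs(table: OnsetPeakTable, model: SegmentModel):
    """Septal-lateral difference of peak circumferential strain, in %.

    Per slice: mean peak strain over the septal segments minus the lateral
    segments; averaged over slices; reported as a magnitude (the sign is
    kept in the second return value).
    """
    per_slice = []
    for row in table.peak_strain:
        a = _wall_mean(row, model, "septal")
        b = _wall_mean(row, model, "lateral")
        if np.isfinite(a) and np.isfinite(b):
            per_slice.append(a - b)
    if not per_slice:
        return None, None
    signed = float(np.mean(per_slice))
    return abs(signed), signed
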