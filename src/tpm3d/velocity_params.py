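"""Scalar dyssynchrony/motion parameters from velocity-time curves:
time-to-peak dispersion (sigma_TTP), asynchrony correlation coefficient
(ACC), global velocity ranges and the temporal uniformity of velocity
(TUV)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import CurveSet, ValidationError

__all__ = [
    "CycleWindows",
    "detect_end_systole",
    "find_peaks",
    "PeakTable",
    "peak_table",
    "sigma_ttp",
    "acc",
    "velocity_range",
    "tuv",
    "fourier_uniformity",
    "pearson",
]


@dataclass
class CycleWindows:
    """Systolic/diastolic search windows within the cardiac cycle (ms)."""

    t_start: float
    t_end_systole: float
    t_end: float
    record: dict = field(default_factory=dict)

    def systolic(self, t):
        return (t >= self.t_start) & (t <= self.t_end_systole)

    def diastolic(self, t):
        return (t > self.t_end_systole) & (t <= self.t_end)


def detect_end_systole(curves: CurveSet, override=None) -> CycleWindows:
    """Locate end-systole on the global longitudinal velocity curve.

    The systolic window runs from the first trigger time to the zero
    crossing following the global longitudinal systolic peak (the whole
    myocardium moves toward the apex during systole, so the global
    longitudinal curve is positive until end-systole); the diastolic
    window is the remainder of the cycle.  If no zero crossing exists the
    window boundary falls back to 40% of the covered span, flagged in the
    record.
    """
    t = curves.time_interp_ms
    if override is not None:
        return CycleWindows(t[0], float(override), t[-1], {"method": "override"})
    g = curves.slice_velocity_interp["l"].mean(axis=0)
    span = t[-1] - t[0]
    if np.allclose(g, 0.0):
        return CycleWindows(t[0], t[0] + 0.4 * span, t[-1], {"method": "fallback_flat"})
    # systolic peak restricted to the first 60% of the cycle
    sel = t <= t[0] + 0.6 * span
    i_pk = int(np.argmax(np.where(sel, g, -np.inf)))
    after = np.where(g[i_pk:] <= 0)[0]
    if len(after) == 0:
        return CycleWindows(
            t[0], t[0] + 0.4 * span, t[-1], {"method": "fallback_no_crossing"}
        )
    i_es = i_pk + int(after[0])
    return CycleWindows(
        t[0], float(t[i_es]), t[-1],
        {"method": "zero_crossing_after_global_longitudinal_peak"},
    )


def find_peaks(time: np.ndarray, values: np.ndarray, windows: CycleWindows):
    """Systolic maximum and diastolic minimum of one interpolated curve.

    Returns (t_peak_sys, v_peak_sys, t_peak_dias, v_peak_dias, flat); on a
    flat curve the peak is the first attainment (window start), flagged.
    """
    sys_sel = windows.systolic(time)
    dia_sel = windows.diastolic(time)
    if not sys_sel.any() or not dia_sel.any():
        raise ValidationError("systole/diastole windows outside the curve span")
    i_s = int(np.argmax(np.where(sys_sel, values, -np.inf)))
    i_d = int(np.argmin(np.where(dia_sel, values, np.inf)))
    flat = bool(np.ptp(values[sys_sel]) == 0.0 and np.ptp(values[dia_sel]) == 0.0)
    return time[i_s], values[i_s], time[i_d], values[i_d], flat


@dataclass
class PeakTable:
    """Per (slice, segment) systolic/diastolic velocity peaks of one direction."""

    t_peak_sys: np.ndarray
    v_peak_sys: np.ndarray
    t_peak_dias: np.ndarray
    v_peak_dias: np.ndarray
    direction: str
    windows: CycleWindows
    n_flat: int = 0


def peak_table(curves: CurveSet, direction: str, n_seg: int, windows: CycleWindows) -> PeakTable:
    """Peak detection over all (slice, segment) interpolated v-t curves."""
    seg = curves.segment_velocity_interp[(direction, n_seg)]
    t = curves.time_interp_ms
    n_sl, n_s, _ = seg.shape
    out = {k: np.zeros((n_sl, n_s)) for k in ("ts", "vs", "td", "vd")}
    n_flat = 0
    for s in range(n_sl):
        for k in range(n_s):
            ts, vs, td, vd, flat = find_peaks(t, seg[s, k], windows)
            out["ts"][s, k], out["vs"][s, k] = ts, vs
            out["td"][s, k], out["vd"][s, k] = td, vd
            n_flat += flat
    return PeakTable(
        t_peak_sys=out["ts"], v_peak_sys=out["vs"],
        t_peak_dias=out["td"], v_peak_dias=out["vd"],
        direction=direction, windows=windows, n_flat=n_flat,
    )


def sigma_ttp(peaks: PeakTable, phase: str, pooling: str = "pooled") -> float:
    """Standard deviation (ms) of the time to peak velocity.

    ``phase`` selects the systolic or diastolic peaks.  The sample (n-1)
    standard deviation is taken over all segments of all slices
    (``pooled``) or as the mean of per-slice standard deviations
    (``per_slice``).
    """
    tp = {"sys": peaks.t_peak_sys, "dias": peaks.t_peak_dias}[phase]
    if tp.size < 2:
        raise ValidationError("sigma_TTP needs at least 2 segments")
    if pooling == "pooled":
        return float(np.std(tp, ddof=1))
    if pooling == "per_slice":
        return float(np.mean([np.std(row, ddof=1) for row in tp]))
    raise ValidationError(f"unknown pooling {pooling!r}")


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation coefficient of two equal-length curves."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    da, db = a - a.mean(), b - b.mean()
    denom = np.sqrt((da**2).sum() * (db**2).sum())
    if denom == 0.0:
        return np.nan
    return float((da * db).sum() / denom)


def acc(curves: CurveSet, direction: str, n_seg: int = 24):
    """Asynchrony correlation coefficient per segment, plus mean/min/max.

    ACC_{i,s} is the Pearson correlation over time between the v-t curve
    of segment i of slice s and the slice-mean v-t curve of slice s.
    Segments with a zero-variance curve are undefined (NaN) and excluded
    from the statistics.  Returns (acc_array (n_sl, n_seg), mean, min,
    max, n_excluded); the statistics are None if every segment is
    undefined.
    """
    seg = curves.segment_velocity_interp[(direction, n_seg)]
    ref = curves.slice_velocity_interp[direction]
    n_sl, n_s, _ = seg.shape
    vals = np.full((n_sl, n_s), np.nan)
    for s in range(n_sl):
        for k in range(n_s):
            vals[s, k] = pearson(seg[s, k], ref[s])
    finite = np.isfinite(vals)
    n_excl = int((~finite).sum())
    if not finite.any():
        return vals, None, None, None, n_excl
    v = vals[finite]
    return vals, float(v.mean()), float(v.min()), float(v.max()), n_excl


def velocity_range(curves: CurveSet, direction: str, windows: CycleWindows) -> float:
    """Global velocity range: mean over slices of (systolic max - diastolic min)."""
    sl = curves.slice_velocity_interp[direction]
    t = curves.time_interp_ms
    ranges = []
    for row in sl:
        _, vs, _, vd, _ = find_peaks(t, row, windows)
        ranges.append(vs - vd)
    return float(np.mean(ranges))


def fourier_uniformity(profiles: np.ndarray):
    """Zero/first-order spatial Fourier uniformity of segment profiles.

    ``profiles`` is (n_sl, n_seg, n_t): a value per segment, per slice and
    time point.  For each slice the magnitudes of the zero- and
    first-order DFT coefficients over the segment index are summed over
    time (S0, S1) and the slice uniformity is S0 / (S0 + S1); the result
    is the mean over slices, in [0, 1].  An identically-zero profile set
    is degenerate and raises.
    """
    profiles = np.asarray(profiles, dtype=float)
    spec = np.fft.fft(profiles, axis=1)
    s0 = np.abs(spec[:, 0, :]).sum(axis=-1)
    s1 = np.abs(spec[:, 1, :]).sum(axis=-1)
    tot = s0 + s1
    if np.all(tot == 0.0):
        raise ValidationError("uniformity undefined: all-zero segment profiles")
    per_slice = np.where(tot > 0, s0 / np.where(tot > 0, tot, 1.0), np.nan)
    return float(np.nanmean(per_slice)), per_slice


def tuv(curves: CurveSet, direction: str, n_seg: int = 24) -> float:
    """Temporal uniformity of velocity for one direction (mean over slices)."""
    profiles = curves.segment_velocity_interp[(direction, n_seg)]
    value, _ = fourier_uniformity(profiles)
    return value
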