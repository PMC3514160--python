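"""One-call analysis driver: dataset in, parameter report + curves out."""

from __future__ import annotations

import numpy as np

from . import deformation_params as dp
from . import velocity_params as vp
from .datamodel import (
    AnalysisConfig,
    CurveSet,
    ParameterReport,
    SegmentModel,
    ValidationError,
    VelocityDataset,
)
from .kinematics import (
    extract_vt_curves,
    rotation_angle_curve,
    strain_curves,
    torsion_rate_curve,
    track_displacement,
)
from .preprocess import (
    assign_segments,
    correct_background_phase,
    decompose_local,
    spline_resample,
)

__all__ = ["run_pipeline"]


def run_pipeline(ds: VelocityDataset, config: AnalysisConfig = None):
    """Run the full motion-quantification pipeline on one dataset.

    Steps: background phase correction (linear fit to static tissue),
    local-direction decomposition, segment assignment, extraction of the
    four curve families, and computation of every scalar parameter.  The
    result is deterministic: repeated runs on the same inputs are
    identical.  Parameters that cannot be computed for a given dataset
    (e.g. torsion with a single slice, correlations of zero-variance
    curves) are left ``None`` with the reason recorded in the report's
    provenance.

    Returns ``(report, curves)``.
    """
    if config is None:
        config = AnalysisConfig()
    ds.validate()
    prov = {"config": config.to_dict(), "not_computable": {}}

    if config.correct_background:
        ds = correct_background_phase(ds)
        prov["background_correction"] = "linear_plane_fit_static_tissue"

    field = decompose_local(ds)
    models = {}
    for n_seg in sorted({config.n_seg_sigma, config.n_seg_uniformity}):
        m = SegmentModel.standard(n_seg, config.angular_origin_deg)
        assign_segments(field, m)
        models[n_seg] = m

    curves = extract_vt_curves(field, tuple(models), config.spline_factor)
    windows = vp.detect_end_systole(curves, config.end_systole_ms)
    prov["windows"] = {
        "t_end_systole_ms": windows.t_end_systole,
        "detection": windows.record,
    }
    report = ParameterReport(provenance=prov)
    t_i = curves.time_interp_ms

    # ---- velocity-time parameters --------------------------------------
    for d in ("l", "r"):
        peaks = vp.peak_table(curves, d, config.n_seg_sigma, windows)
        for phase in ("sys", "dias"):
            setattr(
                report,
                f"sigma_ttp_{phase}_{d}",
                vp.sigma_ttp(peaks, phase, config.sigma_ttp_pooling),
            )
        if peaks.n_flat:
            prov.setdefault("flat_curves", {})[d] = peaks.n_flat
        setattr(report, f"dv_{d}", vp.velocity_range(curves, d, windows))

    acc_maps = {}
    for d in ("l", "r", "c"):
        vals, mean, mn, mx, n_excl = vp.acc(curves, d, config.n_seg_uniformity)
        acc_maps[d] = vals
        setattr(report, f"acc_mean_{d}", mean)
        setattr(report, f"acc_min_{d}", mn)
        setattr(report, f"acc_max_{d}", mx)
        if mean is None:
            prov["not_computable"][f"acc_{d}"] = "all segment curves have zero variance"
        elif n_excl:
            prov.setdefault("acc_excluded_segments", {})[d] = n_excl
        try:
            setattr(report, f"tuv_{d}", vp.tuv(curves, d, config.n_seg_uniformity))
        except ValidationError as e:
            prov["not_computable"][f"tuv_{d}"] = str(e)
    curves.provenance["acc_maps"] = acc_maps

    # ---- torsion rate ---------------------------------------------------
    n_sl = ds.meta.n_slices
    if n_sl >= 2:
        torsion = torsion_rate_curve(field)
        curves.torsion_rate = torsion
        _, curves.torsion_rate_interp = spline_resample(
            curves.time_ms, torsion, config.spline_factor
        )
        report.peak_sys_torsion_rate, report.peak_dias_torsion_rate = dp.torsion_peaks(
            t_i, curves.torsion_rate_interp, windows
        )
    else:
        prov["not_computable"]["torsion"] = "fewer than 2 usable slices"

    # ---- tracking, rotation, strain -------------------------------------
    tracked_u = track_displacement(field, models[config.n_seg_uniformity])
    alpha, n_excl_rot = rotation_angle_curve(tracked_u, field)
    curves.rotation_deg = alpha
    _, curves.rotation_deg_interp = spline_resample(
        curves.time_ms, alpha, config.spline_factor
    )
    if n_excl_rot:
        prov["rotation_excluded_points"] = n_excl_rot

    strain_u = strain_curves(tracked_u)
    for comp in ("circumferential", "radial"):
        key = (comp, config.n_seg_uniformity)
        curves.strain[key] = strain_u[comp]
        _, curves.strain_interp[key] = spline_resample(
            curves.time_ms, strain_u[comp], config.spline_factor
        )

    if config.n_seg_sigma != config.n_seg_uniformity:
        tracked_s = track_displacement(field, models[config.n_seg_sigma])
        strain_s = strain_curves(tracked_s)
        for comp in ("circumferential", "radial"):
            key = (comp, config.n_seg_sigma)
            curves.strain[key] = strain_s[comp]
            _, curves.strain_interp[key] = spline_resample(
                curves.time_ms, strain_s[comp], config.spline_factor
            )

    # ---- rotation-angle parameter (BARC) --------------------------------
    t_rest = dp.detect_rest_phase(curves, windows, config.rest_phase_fraction)
    prov["t_rest_ms"] = t_rest
    if n_sl >= 2:
        b = dp.barc(
            curves.rotation_deg_interp[0], curves.rotation_deg_interp[-1], t_i, t_rest
        )
        report.barc = b
        if b is None:
            prov["not_computable"]["barc"] = "zero-variance rotation curve"
    else:
        prov["not_computable"]["barc"] = "fewer than 2 usable slices"

    # ---- strain-time parameters -----------------------------------------
    circ_u = curves.strain_interp[("circumferential", config.n_seg_uniformity)]
    rad_u = curves.strain_interp[("radial", config.n_seg_uniformity)]
    for comp, arr in (("c", circ_u), ("r", rad_u)):
        try:
            value, _ = vp.fourier_uniformity(np.nan_to_num(arr, nan=0.0))
            setattr(report, f"tus_{comp}", value)
        except ValidationError as e:
            prov["not_computable"][f"tus_{comp}"] = str(e)
    _, report.rvs_max = dp.rvs(circ_u)
    _, report.rvvps_max = dp.rvvps(circ_u)

    circ_s = curves.strain_interp[("circumferential", config.n_seg_sigma)]
    table = dp.onset_peak_times(circ_s, t_i, config.onset_fraction)
    prov["onset_excluded_segments"] = table.n_excluded
    report.sd_t_onset = dp.sd_times(table, "onset")
    report.sd_t_peak = dp.sd_times(table, "peak")
    if report.sd_t_onset is None:
        prov["not_computable"]["sd_t_onset"] = "no shortening segments"

    model_s = models[config.n_seg_sigma]
    os_vec, ps_vec = dp.delay_vectors(table, model_s)
    for vec, tag in ((os_vec, "os"), (ps_vec, "ps")):
        for comp in ("sl", "ia", "ab"):
            v = getattr(vec, comp)
            if comp == "ab" and n_sl < 2:
                v = np.nan
            setattr(report, f"{tag}_delay_{comp}", None if np.isnan(v) else float(v))
    if n_sl < 2:
        prov["not_computable"]["delay_ab"] = "fewer than 2 usable slices"

    report.cv = dp.cv(circ_s, t_i, config.cv_contraction_scope)
    if report.cv is None:
        prov["not_computable"]["cv"] = "mean strain at maximal contraction ~ 0"
    diff_abs, diff_signed = dp.diff_sl_peak_cs(table, model_s)
    report.diff_sl_peak_cs = diff_abs
    if diff_abs is None:
        prov["not_computable"]["diff_sl_peak_cs"] = "septal/lateral peaks unavailable"
    else:
        prov["diff_sl_peak_cs_signed"] = diff_signed

    violations = report.check_bounds()
    if violations:
        prov["bound_violations"] = violations
    return report, curves
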