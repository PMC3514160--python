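"""Shared data types for volumetric tissue-phase-mapping (TPM) analysis.

Conventions used throughout the package
---------------------------------------
* Array axes: velocity arrays are indexed ``(component, phase, slice, row,
  col)`` with components ordered ``x, y, z``.  Slice index 0 is the most
  apical slice; the slice index increases toward the base.
* In-plane physical frame: ``x_mm`` increases with the column index,
  ``y_mm`` decreases with the row index (so +y is "up" in the displayed
  image).  Coordinates are centered on the image center.
* Angles about the blood-pool center are measured from the +y axis
  (anterior/septal junction in the phantom) and increase **clockwise** in
  the viewing orientation; the circumferential velocity is positive for
  clockwise motion, matching the clockwise-positive convention of the
  analysed curves.
* The longitudinal axis points from base toward apex, so motion toward the
  apex is positive.  Because slice index (and physical z) grows toward the
  base, ``v_l = -v_z``.
* Units: positions and voxel sizes in mm, velocities in cm/s, times in ms
  (trigger times from the R-wave), strains reported in %.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, asdict
from typing import Optional

import numpy as np

__all__ = [
    "AcquisitionMeta",
    "VelocityDataset",
    "SegmentModel",
    "AnalysisConfig",
    "LocalVelocityField",
    "CurveSet",
    "TrackedPoints",
    "ParameterReport",
    "WALL_GROUPS",
]

COMPONENTS = ("x", "y", "z")
DIRECTIONS = ("l", "r", "c")

#: Anatomical wall groups used for the delay vectors.
WALL_GROUPS = {
    "septal": ("inferoseptal", "anteroseptal"),
    "lateral": ("inferolateral", "anterolateral"),
    "inferior": ("inferior",),
    "anterior": ("anterior",),
}

# 6-segment wall labels in clockwise order starting at the angular origin
# (+y, image top).  The bullseye layout puts the septal wall at the top, the
# inferior wall on the right, the lateral wall at the bottom and the anterior
# wall on the left, i.e. septal -> anterior -> lateral -> inferior running
# counterclockwise.
LABELS_6 = (
    "inferoseptal",   # [0, 60) deg
    "inferior",       # [60, 120)
    "inferolateral",  # [120, 180)
    "anterolateral",  # [180, 240)
    "anterior",       # [240, 300)
    "anteroseptal",   # [300, 360)
)


class ValidationError(ValueError):
    """A dataset or configuration violated a structural invariant."""


@dataclass
class AcquisitionMeta:
    """Acquisition metadata of a TPM velocity dataset.

    Defaults correspond to a volunteer-style protocol: 25 cardiac phases at
    a 37.3 ms phase interval, 21 slices of 3 mm isotropic voxels, velocity
    encoding limit (VENC) 20 cm/s.
    """

    voxel_size_mm: tuple = (3.0, 3.0, 3.0)
    phase_interval_ms: float = 37.3
    n_phases: int = 25
    n_slices: int = 21
    venc_cm_s: float = 20.0
    slice_order: str = "apex_to_base"
    trigger_time_ms: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.n_phases < 3:
            raise ValidationError("n_phases must be >= 3")
        if self.phase_interval_ms <= 0:
            raise ValidationError("phase_interval_ms must be positive")
        if self.venc_cm_s <= 0:
            raise ValidationError("venc_cm_s must be positive")
        if self.slice_order not in ("apex_to_base", "base_to_apex"):
            raise ValidationError(f"unknown slice_order {self.slice_order!r}")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if self.trigger_time_ms is None:
            self.trigger_time_ms = np.arange(self.n_phases) * self.phase_interval_ms
        else:
            self.trigger_time_ms = np.asarray(self.trigger_time_ms, dtype=float)
            if self.trigger_time_ms.shape != (self.n_phases,):
                raise ValidationError("trigger_time_ms must have one entry per phase")
            d = np.diff(self.trigger_time_ms)
            if np.any(d <= 0):
                raise ValidationError("trigger_time_ms must be strictly increasing")
            if not np.allclose(d, self.phase_interval_ms, rtol=1e-6):
                raise ValidationError(
                    "trigger_time_ms spacing must equal phase_interval_ms"
                )

    @property
    def cycle_length_ms(self) -> float:
        """Nominal RR interval covered by the acquisition."""
        return self.n_phases * self.phase_interval_ms

    def to_dict(self) -> dict:
        d = asdict(self)
        d["trigger_time_ms"] = self.trigger_time_ms.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionMeta":
        d = dict(d)
        if d.get("trigger_time_ms") is not None:
            d["trigger_time_ms"] = np.asarray(d["trigger_time_ms"], dtype=float)
        return cls(**d)


@dataclass
class VelocityDataset:
    """A 4D three-directional velocity field with masks and contours.

    ``velocities`` is indexed ``(component, phase, slice, row, col)`` in
    cm/s; ``myo_mask`` is boolean per ``(phase, slice, row, col)``;
    ``static_mask`` is boolean per ``(slice, row, col)``; contours are
    ordered in-plane point lists in centered mm coordinates with shape
    ``(phase, slice, n_points, 2)`` storing ``(x_mm, y_mm)``.  Internally
    slice index 0 is always the most apical slice; readers normalise
    base-to-apex files on load.
    """

    velocities: np.ndarray
    myo_mask: np.ndarray
    static_mask: np.ndarray
    endo_contours: np.ndarray
    epi_contours: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self):
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.myo_mask = np.asarray(self.myo_mask, dtype=bool)
        self.static_mask = np.asarray(self.static_mask, dtype=bool)
        self.endo_contours = np.asarray(self.endo_contours, dtype=float)
        self.epi_contours = np.asarray(self.epi_contours, dtype=float)

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self):
        return self.velocities.shape

    @property
    def grid_shape(self):
        """(n_rows, n_cols) of the in-plane grid."""
        return self.velocities.shape[-2:]

    def inplane_coords_mm(self):
        """Centered physical coordinates (x_mm, y_mm) of every voxel.

        Returns two (n_rows, n_cols) arrays.  +x is to the right (columns),
        +y is up (decreasing row index).
        """
        ny, nx = self.grid_shape
        dy, dx = self.meta.voxel_size_mm[1], self.meta.voxel_size_mm[0]
        cols = (np.arange(nx) - (nx - 1) / 2.0) * dx
        rows = ((ny - 1) / 2.0 - np.arange(ny)) * dy
        x_mm = np.broadcast_to(cols[None, :], (ny, nx))
        y_mm = np.broadcast_to(rows[:, None], (ny, nx))
        return x_mm, y_mm

    # -- validation -------------------------------------------------------
    def validate(self) -> "VelocityDataset":
        m = self.meta
        nc, nph, nsl, ny, nx = self.velocities.shape
        if nc != 3:
            raise ValidationError("velocities must have 3 components (x, y, z)")
        if nph != m.n_phases or nsl != m.n_slices:
            raise ValidationError(
                f"velocity array shape {self.velocities.shape} inconsistent with "
                f"meta (n_phases={m.n_phases}, n_slices={m.n_slices})"
            )
        if self.myo_mask.shape != (nph, nsl, ny, nx):
            raise ValidationError(
                f"myo_mask shape {self.myo_mask.shape} != {(nph, nsl, ny, nx)}"
            )
        if self.static_mask.shape != (nsl, ny, nx):
            raise ValidationError(
                f"static_mask shape {self.static_mask.shape} != {(nsl, ny, nx)}"
            )
        for name, c in (("endo", self.endo_contours), ("epi", self.epi_contours)):
            if c.ndim != 4 or c.shape[:2] != (nph, nsl) or c.shape[3] != 2:
                raise ValidationError(
                    f"{name}_contours must have shape (n_phases, n_slices, n_pts, 2)"
                )
        if not self.myo_mask.any(axis=(-2, -1)).all():
            raise ValidationError("myo_mask empty for at least one (phase, slice)")
        vmax = np.abs(self.velocities).max()
        if vmax > m.venc_cm_s * (1 + 1e-9):
            warnings.warn(
                f"velocity magnitude {vmax:.2f} cm/s exceeds VENC "
                f"{m.venc_cm_s:.2f} cm/s (possible aliasing)",
                stacklevel=2,
            )
        # endo strictly inside epi: compare radii about the endo centroid
        ec = self.endo_contours
        pc = self.epi_contours
        ctr = ec.mean(axis=2, keepdims=True)
        r_endo = np.linalg.norm(ec - ctr, axis=-1).max(axis=-1)
        r_epi = np.linalg.norm(pc - ctr, axis=-1).min(axis=-1)
        if np.any(r_endo >= r_epi):
            raise ValidationError("endocardial contour not strictly inside epicardial")
        return self

    def equals(self, other: "VelocityDataset", rtol=0.0, atol=0.0) -> bool:
        ok = (
            np.allclose(self.velocities, other.velocities, rtol=rtol, atol=atol)
            and np.array_equal(self.myo_mask, other.myo_mask)
            and np.array_equal(self.static_mask, other.static_mask)
            and np.allclose(self.endo_contours, other.endo_contours, rtol=rtol, atol=atol)
            and np.allclose(self.epi_contours, other.epi_contours, rtol=rtol, atol=atol)
        )
        sm, om = self.meta, other.meta
        ok = ok and sm.voxel_size_mm == om.voxel_size_mm
        ok = ok and np.isclose(sm.phase_interval_ms, om.phase_interval_ms)
        ok = ok and sm.n_phases == om.n_phases and sm.n_slices == om.n_slices
        ok = ok and np.isclose(sm.venc_cm_s, om.venc_cm_s)
        ok = ok and np.allclose(sm.trigger_time_ms, om.trigger_time_ms)
        return bool(ok)

    def copy(self) -> "VelocityDataset":
        return VelocityDataset(
            velocities=self.velocities.copy(),
            myo_mask=self.myo_mask.copy(),
            static_mask=self.static_mask.copy(),
            endo_contours=self.endo_contours.copy(),
            epi_contours=self.epi_contours.copy(),
            meta=AcquisitionMeta.from_dict(self.meta.to_dict()),
        )


@dataclass
class SegmentModel:
    """Angular division of a short-axis slice into myocardial segments.

    Segments are contiguous angular bins of equal width.  Bin 0 starts at
    ``angular_origin_deg`` (default 0 = image top, +y) and bins are ordered
    clockwise.  Each segment carries an anatomical wall label; the
    24-segment model refines the 6-segment model 4:1 so labels collapse
    consistently.
    """

    n_seg: int
    boundaries_deg: np.ndarray
    labels: tuple
    angular_origin_deg: float = 0.0

    @classmethod
    def standard(cls, n_seg: int, angular_origin_deg: float = 0.0) -> "SegmentModel":
        if n_seg not in (6, 24):
            raise ValidationError("n_seg must be 6 or 24")
        bounds = np.linspace(0.0, 360.0, n_seg + 1)
        if n_seg == 6:
            labels = LABELS_6
        else:
            labels = tuple(LABELS_6[j // 4] for j in range(24))
        return cls(
            n_seg=n_seg,
            boundaries_deg=bounds,
            labels=labels,
            angular_origin_deg=angular_origin_deg,
        )

    def assign(self, theta_deg: np.ndarray) -> np.ndarray:
        """Segment index of each angle (degrees, any range)."""
        th = np.mod(np.asarray(theta_deg, dtype=float) - self.angular_origin_deg, 360.0)
        width = 360.0 / self.n_seg
        ids = np.floor(th / width).astype(int)
        return np.clip(ids, 0, self.n_seg - 1)

    def centers_deg(self) -> np.ndarray:
        width = 360.0 / self.n_seg
        return self.angular_origin_deg + (np.arange(self.n_seg) + 0.5) * width

    def segments_of_wall(self, wall: str) -> np.ndarray:
        """Indices of all segments belonging to an anatomical wall group."""
        members = WALL_GROUPS[wall]
        return np.array([i for i, lab in enumerate(self.labels) if lab in members])


@dataclass
class AnalysisConfig:
    """Tunable choices of the analysis pipeline.

    Defaults follow the conventions used for the reported parameter set:
    6 segments for time-to-peak / onset statistics, 24 segments for the
    uniformity and variance indices, natural cubic splines with 8x temporal
    upsampling, onset threshold at 10% of a segment's own peak shortening.
    """

    n_seg_sigma: int = 6          # sigma_TTP, SD(T_onset/T_peak), CV, delays
    n_seg_uniformity: int = 24    # ACC, TUV, TUS, RVS, RVVPS
    spline_factor: int = 8
    onset_fraction: float = 0.1
    rest_phase_fraction: float = 0.1   # |v| threshold for the diastolic resting phase
    end_systole_ms: Optional[float] = None   # override the automatic detection
    sigma_ttp_pooling: str = "pooled"  # "pooled" over all slices or "per_slice"
    cv_contraction_scope: str = "global"  # "global" or "per_slice" mean-strain minimum
    angular_origin_deg: float = 0.0
    correct_background: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class LocalVelocityField:
    """Voxel velocities re-expressed in local myocardial directions.

    ``v_l`` (longitudinal, toward apex positive), ``v_r`` (radial, toward
    the blood-pool center positive) and ``v_c`` (circumferential, clockwise
    positive) are dense ``(phase, slice, row, col)`` arrays, defined on the
    myocardial mask and zero elsewhere.  ``theta_deg`` / ``radius_mm`` hold
    each voxel's polar coordinates about the per-(phase, slice) blood-pool
    center; ``segment_ids`` maps each configured segment count to a dense
    id array (-1 outside the mask).
    """

    v_l: np.ndarray
    v_r: np.ndarray
    v_c: np.ndarray
    mask: np.ndarray
    centers_mm: np.ndarray          # (phase, slice, 2) as (x, y)
    theta_deg: np.ndarray
    radius_mm: np.ndarray
    meta: AcquisitionMeta
    segment_ids: dict = field(default_factory=dict)
    segment_models: dict = field(default_factory=dict)
    endo_contours: Optional[np.ndarray] = None
    epi_contours: Optional[np.ndarray] = None

    def component(self, direction: str) -> np.ndarray:
        return {"l": self.v_l, "r": self.v_r, "c": self.v_c}[direction]


@dataclass
class CurveSet:
    """All extracted time curves on both the raw and interpolated grids.

    Velocity curves are stored per slice and per (slice, segment); rotation
    angles per slice; the torsion-rate curve is global; strain curves per
    (slice, segment) and strain component.  Keys of the per-segment dicts
    are ``(direction, n_seg)`` for velocities and ``(component, n_seg)``
    for strain where component is ``"circumferential"`` or ``"radial"``.
    Strain is stored in %.
    """

    time_ms: np.ndarray
    time_interp_ms: np.ndarray
    slice_velocity: dict = field(default_factory=dict)        # dir -> (n_sl, n_t)
    slice_velocity_interp: dict = field(default_factory=dict)
    segment_velocity: dict = field(default_factory=dict)      # (dir, n_seg) -> (n_sl, n_seg, n_t)
    segment_velocity_interp: dict = field(default_factory=dict)
    rotation_deg: Optional[np.ndarray] = None                 # (n_sl, n_t)
    rotation_deg_interp: Optional[np.ndarray] = None
    torsion_rate: Optional[np.ndarray] = None                 # (n_t,) deg/(cm s)
    torsion_rate_interp: Optional[np.ndarray] = None
    strain: dict = field(default_factory=dict)                # (comp, n_seg) -> (n_sl, n_seg, n_t) in %
    strain_interp: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


@dataclass
class TrackedPoints:
    """Forward-tracked material points of one segment model.

    Per (slice, segment) and phase: the segment-center centerline point,
    the pair of centerline chord points bounding the segment (seeded just
    inside its angular boundaries), and the endo/epi normal pair at the
    segment center.  All positions are (x, y) mm in the centered in-plane
    frame.  ``provenance`` records the integration rule and time step.
    """

    center: np.ndarray       # (n_sl, n_seg, n_ph, 2)
    chord_a: np.ndarray      # (n_sl, n_seg, n_ph, 2)
    chord_b: np.ndarray      # (n_sl, n_seg, n_ph, 2)
    endo: np.ndarray         # (n_sl, n_seg, n_ph, 2)
    epi: np.ndarray          # (n_sl, n_seg, n_ph, 2)
    model: SegmentModel = None
    truncated: np.ndarray = None   # (n_sl, n_seg) bool: left the grid
    provenance: dict = field(default_factory=dict)


# Parameter report -----------------------------------------------------------

_REPORT_UNITS = {
    "sigma_ttp_sys_l": "ms", "sigma_ttp_dias_l": "ms",
    "sigma_ttp_sys_r": "ms", "sigma_ttp_dias_r": "ms",
    "acc_mean_l": "", "acc_mean_r": "", "acc_mean_c": "",
    "acc_min_l": "", "acc_min_r": "", "acc_min_c": "",
    "acc_max_l": "", "acc_max_r": "", "acc_max_c": "",
    "dv_l": "cm/s", "dv_r": "cm/s",
    "tuv_l": "", "tuv_r": "", "tuv_c": "",
    "peak_sys_torsion_rate": "deg/(cm s)",
    "peak_dias_torsion_rate": "deg/(cm s)",
    "barc": "",
    "tus_c": "", "tus_r": "",
    "rvs_max": "%^2", "rvvps_max": "%",
    "sd_t_onset": "ms", "sd_t_peak": "ms",
    "cv": "%", "diff_sl_peak_cs": "%",
    "os_delay_sl": "ms", "os_delay_ia": "ms", "os_delay_ab": "ms",
    "ps_delay_sl": "ms", "ps_delay_ia": "ms", "ps_delay_ab": "ms",
}


@dataclass
class ParameterReport:
    """Scalar motion / dyssynchrony parameters of one dataset.

    Velocity-based: time-to-peak dispersion (sigma_TTP), asynchrony
    correlation coefficient (ACC) statistics, global velocity ranges (dv),
    temporal uniformity of velocity (TUV), peak torsion rates.
    Displacement-based: base-apex rotation correlation (BARC), temporal
    uniformity of strain (TUS, circumferential = CURE), regional strain
    variance (RVS) and its square root (RVVPS), onset/peak-of-shortening
    dispersion and delay vectors, coefficient of variation (CV) and the
    septal-lateral peak-strain difference.  A value of ``None`` means
    not computable for this dataset; the reason is in ``provenance``.
    """

    sigma_ttp_sys_l: Optional[float] = None
    sigma_ttp_dias_l: Optional[float] = None
    sigma_ttp_sys_r: Optional[float] = None
    sigma_ttp_dias_r: Optional[float] = None
    acc_mean_l: Optional[float] = None
    acc_mean_r: Optional[float] = None
    acc_mean_c: Optional[float] = None
    acc_min_l: Optional[float] = None
    acc_min_r: Optional[float] = None
    acc_min_c: Optional[float] = None
    acc_max_l: Optional[float] = None
    acc_max_r: Optional[float] = None
    acc_max_c: Optional[float] = None
    dv_l: Optional[float] = None
    dv_r: Optional[float] = None
    tuv_l: Optional[float] = None
    tuv_r: Optional[float] = None
    tuv_c: Optional[float] = None
    peak_sys_torsion_rate: Optional[float] = None
    peak_dias_torsion_rate: Optional[float] = None
    barc: Optional[float] = None
    tus_c: Optional[float] = None
    tus_r: Optional[float] = None
    rvs_max: Optional[float] = None
    rvvps_max: Optional[float] = None
    sd_t_onset: Optional[float] = None
    sd_t_peak: Optional[float] = None
    cv: Optional[float] = None
    diff_sl_peak_cs: Optional[float] = None
    os_delay_sl: Optional[float] = None
    os_delay_ia: Optional[float] = None
    os_delay_ab: Optional[float] = None
    ps_delay_sl: Optional[float] = None
    ps_delay_ia: Optional[float] = None
    ps_delay_ab: Optional[float] = None
    provenance: dict = field(default_factory=dict)

    PARAMETER_NAMES = tuple(_REPORT_UNITS)
    UNITS = dict(_REPORT_UNITS)

    def to_dict(self, include_provenance: bool = True) -> dict:
        d = {k: getattr(self, k) for k in self.PARAMETER_NAMES}
        if include_provenance:
            d["provenance"] = self.provenance
        return d

    def to_dataframe(self):
        import pandas as pd

        rows = [
            {"parameter": k, "value": getattr(self, k), "unit": self.UNITS[k]}
            for k in self.PARAMETER_NAMES
        ]
        return pd.DataFrame(rows)

    def check_bounds(self) -> list:
        """Return a list of violated range invariants (empty when valid)."""
        bad = []

        def _chk(name, lo, hi):
            v = getattr(self, name)
            if v is not None and not (lo - 1e-9 <= v <= hi + 1e-9):
                bad.append(f"{name}={v} outside [{lo}, {hi}]")

        for d in DIRECTIONS:
            for stat in ("mean", "min", "max"):
                _chk(f"acc_{stat}_{d}", -1.0, 1.0)
            _chk(f"tuv_{d}", 0.0, 1.0)
        _chk("barc", -1.0, 1.0)
        _chk("tus_c", 0.0, 1.0)
        _chk("tus_r", 0.0, 1.0)
        for name in ("rvs_max", "rvvps_max", "sd_t_onset", "sd_t_peak"):
            v = getattr(self, name)
            if v is not None and v < -1e-9:
                bad.append(f"{name}={v} negative")
        return bad
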