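# Methods

## Coordinate and sign conventions

Velocity arrays are indexed `(component, phase, slice, row, col)` with slice
0 the most apical slice (files declaring base-first order are flipped on
read and the original order recorded). In-plane, +x runs along columns and
+y up the displayed image; angles about the blood-pool center are measured
from +y and increase clockwise in the viewing orientation. The longitudinal
axis points from base toward apex, so the systolic descent of the base is
positive and `v_l = -v_z`. Radial velocity is positive toward the blood-pool
center: the radial velocity-time curves then show positive systolic lobes
(systolic inward motion), which fixes the sign convention the peak detectors
assume. Circumferential velocity is positive for clockwise motion in the
viewing orientation. Positions are mm, velocities cm/s, times ms from the
R-wave, strains %.

Anatomically, the angular origin (+y) is taken as the septal wall center:
clockwise from the top the 6-segment model reads inferoseptal, inferior,
inferolateral, anterolateral, anterior, anteroseptal, which puts the septal
wall at the top of a bullseye, the inferior wall on the right, the lateral
wall at the bottom and the anterior wall on the left. The 24-segment model
refines each wall 4:1 so the two models collapse consistently. Delay-vector
wall groups: septal = {infero-, anteroseptal}, lateral =
{infero-, anterolateral}.

## The analytic beating-LV phantom

Each slice is an annulus whose endo-/epicardial radii follow
`R(z,t) = R0(z) * (1 - e * g(t))`, where `g` is a two-lobe raised-cosine
contraction shape: `g` rises 0→1 over the systolic interval (default 35% of
the cycle), relaxes back over the next 30%, and rests (diastasis) for the
remainder. Its derivative is continuous, giving the classic
positive-systolic / negative-diastolic velocity waveform. The annulus
rotates rigidly per slice with amplitude linear in z (defaults +8° apical,
−4° basal in the clockwise-positive convention, producing systolic twist and
diastolic untwist and a positive systolic torsion rate), and translates
longitudinally with amplitude linear in z (15 mm base, 3 mm apex). Voxel
velocities are the analytic material velocities sampled at voxel centers:
radial rates interpolate linearly across the wall between the endo and epi
radius rates (endo excursion 22%, epi 8%, so the wall thickens in systole,
radial strain ≈ +29%, mid-wall circumferential strain ≈ −14%).

Per-segment activation delays shift that segment's velocity waveform in time
(and scale its amplitude if configured); the geometry — masks and contours,
which are exact circles — remains axisymmetric, but a delayed segment's
transmural coordinate is computed against its own delayed radii so its
velocity field is internally consistent. This makes per-segment onset times
exact ground truth: onset of shortening at fraction f of peak is
`tau + (t_sys/pi) * arccos(1 - 2f)`.

Measurement imperfections emulated: i.i.d. Gaussian velocity noise
(default 0.3 cm/s for the presets, a typical TPM noise level at VENC
20–30 cm/s) added everywhere, and a per-slice linear background-phase plane
added to myocardium and static tissue alike. A 4-voxel border frame of
static tissue surrounds the heart. Not emulated: Rician/phase-wrap noise
statistics, through-plane motion artifacts, trabeculation, contour
segmentation error (contours are exact). Passing tests therefore demonstrate
correctness of the analysis chain under known kinematics, not robustness to
segmentation error or aliasing.

Geometry and sampling defaults match a volunteer-style protocol: 25 phases
at 37.3 ms, 21 slices of 3 mm isotropic voxels on a 128² grid, VENC
20 cm/s. Presets: `healthy` (defaults), `dcm_like` (all motion amplitudes
halved, synchronous), `lbbb_like` (amplitudes ~30% reduced, lateral wall
delayed 150 ms and scaled to 60%, apex and base co-rotating).

## Pipeline numerics

* **Background phase correction.** Per component, phase and slice, a plane
  `a + b x + c y` is least-squares fitted to the static voxels in
  image-center-centered mm coordinates (decorrelating offset and slopes) and
  subtracted from the whole slice. Collinear static voxels trigger a
  constant-offset fallback with a warning. The operation is idempotent to
  numerical precision.
* **Temporal interpolation.** Natural cubic splines through the trigger-time
  samples, resampled at 8× density (grid step 4.7 ms at Δt 37.3 ms), keeping
  peak/onset-time quantisation below ~5 ms. All peak and onset detection
  operates on this grid; splines pass exactly through the samples.
* **Segment assignment** is Eulerian: recomputed each phase about that
  phase's endocardial-contour centroid.
* **Systole/diastole windows.** End-systole is the zero crossing of the
  global (all-slice mean) longitudinal velocity curve after its systolic
  peak; fallback 40% of the covered span, flagged. Override via
  `AnalysisConfig.end_systole_ms`.
* **Diastolic resting phase** (for BARC): first time after the global
  diastolic longitudinal peak where the global speed |v| stays below 10% of
  its cycle maximum for ≥ 2 consecutive interpolated samples; fallback cycle
  end. The threshold fraction is configurable.
* **Tracking.** Explicit forward Euler with the acquisition Δt, exactly the
  displacement summation rule — no higher-order scheme, so the tracking
  error is first-order (halving the phase interval halves it; verified).
  Tracked points per (slice, segment): the segment-center centerline point,
  two chord points seeded 5% of the span inside the segment's angular
  boundaries, and an endo/epi pair on the segment-center radial. Velocities
  are looked up in 24 fixed 15° occupancy bins (finer than any strain
  model, so the chord endpoints of one segment sample distinct bins);
  within a bin the inward-radial and circumferential components are fitted
  linearly in radius and evaluated at the point's own angle and radius.
  A single mean vector per segment would translate the endo/epi pair
  rigidly (no radial strain at all) and applies the bin's mean direction to
  points up to half a bin away, which measured as a ~20% systematic strain
  error; the transmural linear fit reduces to the bin mean at the bin
  centroid while preserving direction and gradient. Points leaving the
  image grid are frozen and flagged. Tracking is in-plane only; the
  longitudinal component feeds the velocity parameters.
* **Rotation angle** per slice: mean over segments of the unwrapped change
  in polar angle of the tracked center points about the current blood-pool
  center, clockwise positive; points within half a voxel of the center are
  excluded.
* **Torsion rate.** ω per slice is the voxel-wise mean of v_c/r (exact for
  rigid rotation, unlike mean(v_c)/mean(r)); r̄ is the time-averaged mean
  myocardial radius; the most apical and most basal slices are used, and the
  normalisation (r_a + r_b)/(2d) follows the classic convention.
* **Strain** is cumulative relative to phase 0 (end-diastole):
  circumferential from the chord length between a segment's two tracked
  boundary points, radial from the tracked endo–epi pair distance (the
  pair-distance reading of the normal-vector definition), both in %.
  Cumulative (not incremental) strain is used because onset/peak-of-
  shortening parameters need a quantity monotone until peak. Degenerate
  chords (< 0.1 mm) are flagged.
* **Statistics.** Pearson correlations use the standard product-moment
  denominator (the [−1, 1] range requires it). Uniformity indices use
  magnitudes of complex DFT coefficients, guaranteeing TUV/TUS ∈ [0, 1].
  All SDs/variances are sample (n−1) statistics — segment counts are small.
  σ_TTP and SD(T_onset/peak) pool segments across slices (per-slice
  averaging is a config switch). Onset of shortening: first time a
  segment's circumferential strain falls below 10% of its own peak
  (configurable fraction, echoed in provenance); never-shortening segments
  are excluded and counted. CV evaluates at the global mean-strain minimum
  (per-slice variant configurable). DiffSLPeakCS is reported as a
  magnitude with the sign kept in provenance.
* Parameters that are undefined for a dataset (zero-variance curves, a
  single slice for torsion/BARC/apex–base delays, no shortening segments)
  are reported as `None` with the reason in the report provenance; the rest
  of the report is still computed.

## Problem sizes

The test suite exercises reduced phantoms chosen to keep discretisation
honest while remaining quick: 5 slices × 25 phases × 64² voxels (3 mm) for
noise-free recovery checks, 7 slices with noise for the preset contrasts,
1.5 mm voxels where voxel-sampling convergence itself is under test. The
acceptance script runs the presets at the full default scale (21 × 25 ×
128²). All randomness is seeded; pipeline runs are bit-reproducible.

## Known limitations

* Euler tracking is first-order: rotation-angle curves lag the analytic
  truth by up to ~Δt · peak angular rate (≈1° at default settings), and the
  noise-free cycle-closure drift is 0.7% (circumferential) / 1.1% (radial —
  the endo/epi pair spans the steepest transmural gradient). Both halve
  when the phase count doubles.
* Under bulk in-plane translation, the per-bin polar decomposition can
  rotate the reconstructed velocity of a tracked point by up to half a bin
  width (7.5°); the transverse displacement error is bounded by
  displacement × sin(7.5°). The LV analyses here are rotation/deformation
  centred, but heavy bulk motion would need a translation-aware tracker.
* Tracking linearity (velocities scaled by k ⇒ displacements scaled by k)
  holds exactly for the first step and approximately thereafter, because
  occupancy-bin membership is path-dependent.
* Radial strain uses the endo–epi pair distance; a fixed-length normal
  probe would weight transmural gradients differently.
* The phantom's per-segment delays shift velocity waveforms but leave the
  contour geometry axisymmetric; contour-derived quantities (centers,
  seed radii) are therefore exact while a real delayed wall would also
  deform its contours.
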