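# Methods

`axialkin` measures how fishes rotate the head and vertebral column during
feeding strikes, from marker-based skeletal motion capture, and validates the
whole measurement chain against a forward-kinematics simulator. This note
documents the models, conventions, parameters and their rationale, plus known
limitations.

## Measurement model

### Rigid-body poses from markers

Each bone carries a constellation of bone-fixed markers whose reference
positions (from a CT scan of the animal) are known in the bone's own frame.
Given the observed world positions of those markers in a video frame, the
bone's pose `T = [R | t]` (world-from-bone, mm) is the least-squares
superposition: the proper rotation `R` and translation `t` minimising
`Σ_i ‖R x_i + t − y_i‖²`. We use the closed-form SVD solution (Kabsch /
orthogonal Procrustes) with the determinant correction that excludes
reflections. Markers missing in a frame are dropped; a frame with fewer than
three usable markers, or a collinear constellation, yields a tracking gap
rather than a pose. Collinearity is judged by the *second* singular value of
the centered constellation (> 1e-6 mm required): coplanar marker sets — e.g.
a midsagittal body plane — are perfectly valid for pose fitting, only
collinear ones are degenerate.

Tracking precision is the standard marker-based metric: for every unordered
marker pair, the sample standard deviation over frames of the inter-marker
distance, averaged over pairs. Rigid noise-free motion gives exactly zero;
independent isotropic Gaussian noise of s.d. σ per axis on each marker gives
σ√2 in expectation (≈ 0.042 mm at σ = 0.03 mm).

### Zero-phase low-pass filtering

Pose sequences are filtered, not raw marker paths: the three translations
and the rotation as a unit quaternion (sign continuity enforced, renormalised
afterwards) pass through a second-order Butterworth applied forward and
backward (`filtfilt`), doubling the effective order and cancelling phase lag
so event timing (e.g. the peak-elevation frame) is preserved. Quaternions are
used instead of Euler angles to avoid gimbal artifacts in the filtered
parameters. Edges are padded by reflection ("even" padding) of length 3 ×
order; we measured this to be near the one-sided optimum for edge noise
(point-reflection/"odd" padding roughly doubles the edge noise s.d.). Gaps
split a sequence into independently filtered segments; segments of at most
3 × order frames pass through unfiltered with a warning. Defaults: order 2,
cut-off 60 Hz at 500 fps (trout preset) and 100 Hz at 1000 fps (frogfish
preset, the low end of the plausible 100–200 Hz range, overridable).

Even with reflection padding, the first and last frames of a filtered
segment carry ~1.3× the interior noise s.d.; recordings should therefore
bracket the strike with lead-in and trailing margin, which the simulator's
default windows do.

### Joint coordinate systems

Anatomical coordinate systems (ACSs) follow the fish convention: +x cranial,
+y dorsal, +z to the animal's left, right-handed. An ACS can be constructed
from centrum geometry (origin at the midpoint of the endplate centroids, x
along the centrum axis, y the orthogonalised direction to a dorsal landmark,
z = x × y). A joint coordinate system (JCS) pairs one ACS on the cranial
bone with one on the caudal bone, placed coincidently in the reference (CT)
pose so all six degrees of freedom are zero at reference.

Per frame, the relative transform `T = inv(world_from_proximal_ACS) ·
world_from_distal_ACS` is decomposed with the intrinsic z–y–x Euler sequence
`T_rot = Rz(γ) Ry(β) Rx(α)`: γ is dorsoventral rotation in the sagittal
plane, β lateral rotation, α axial roll; translations are the distal origin
expressed in the proximal frame. For chain joints (craniovertebral = joint 1,
then intervertebral joints), the caudal bone's z rotation relative to its
cranial neighbour is negative for dorsal motion, so reported `rot_z` is
`−γ` — dorsal (extension) positive. Cranial elevation uses a JCS between the
body plane (proximal) and the neurocranium (distal) with no sign flip:
positive z is elevation directly. With this one embedding both published
sign conventions fall out of a single `sign_flip_z` parameter.

Frames with |β| within 0.5° of 90° are flagged as gimbal-proximal; at exact
lock the decomposition resolves the degeneracy with α = 0 (the scipy
convention). The intrinsic reading of "z–y–x" is a documented choice; for
near-planar (sagittal) motion the intrinsic and extrinsic readings give
identical `rot_z`, they differ only for large mixed rotations.

### Strike-level measures

* **Elevation trace** — per-frame `rot_z` of the elevation JCS minus its
  frame-0 value; peak is its maximum. Onset is the first frame where the
  trace exceeds 5% of its peak and stays above for ≥ 5 frames; reported
  duration runs from onset to peak. Onset detection is only used for event
  timing and trace alignment — *deltas are always taken relative to frame 0*
  (the initial value), so programmed rotations are recovered exactly.
* **Inclusion rule** — a strike is analysed iff peak elevation ≥ 5°
  (boundary inclusive).
* **Joint deltas at peak** — per-joint `rot_z(peak frame) − rot_z(frame 0)`.
* **Curvature profile** — dorsoventral (y) translations of virtual landmarks
  (the craniovertebral joint point for the neurocranium, centrum centroids
  for vertebrae) expressed in an ACS fixed to the caudal-most modelled
  vertebra, baseline-subtracted at frame 0. "Translation per centrum" is the
  caudal-neighbour first difference `y(k) − y(k+1)` of that profile — a
  discrete curvature measure whose steps vanish caudal of a rotating joint
  and are equal within a rigidly rotating section.
* **Cohort summary** — mean, standard error (sample s.d./√n over strikes),
  maximum, n; n = 1 is flagged and reports s.e. 0. Mean traces are averaged
  at each onset-aligned time step over the strikes present there; steps with
  fewer than two strikes are dropped.

## The synthetic chain simulator

Because the pipeline's real inputs (X-ray video reconstructions) are not
distributable, validation uses a forward-kinematics simulator whose ground
truth is exact by construction.

The chain is the neurocranium plus N vertebrae laid cranially along +x; the
caudal-most vertebra is the fixed base. Joint k sits at the cranial endplate
of vertebra k. Programmed joint angles are expressed directly in the
measurement convention (the relative distal-in-proximal rotation is
`Rz(−θz) Ry(θy) Rx(θx)`), so the pipeline recovers the programs identically
— the round trip checks the measurement chain, not a sign bookkeeping.
Angle ramps are smoothstep (C¹, band-limited, filter-friendly). Whole-body
motion (translation of everything including the body plane) can be
superimposed; body-referenced measures are invariant to it. Marker noise is
additive isotropic Gaussian per axis with optional independent dropout;
ground-truth poses are retained noise-free.

### Presets (the simulated study conditions)

* **trout** — 25 modelled (cranial) vertebrae of uniform 5 mm centra behind a
  60 mm neurocranium, straight reference column, 500 fps, 60 Hz cut-off,
  six midsagittal body-plane markers in two rows, whole-body drift
  (250, 40, 0) mm/s. Default program: dorsal rotations ≤ 1.9° over joints
  1–12 summing to ~11.3°, onset 20 ms, rise 80 ms — many small rotations
  producing 10–15° of elevation.
* **frogfish** — 18 vertebrae with centra graded 9 → 4 mm behind a 50 mm
  neurocranium, an initially S-curved column (cranial joints flexed −5…−2°,
  mid-caudal joints extended +2…+3°), 1000 fps, 100 Hz cut-off, six
  bilateral body-plane markers, stationary body. Default program: 18° and
  24° at the craniovertebral and first intervertebral joints, small dorsal
  rotations at joints 3–6, ventral rotation at joints 7–9, summing to ~45°;
  onset 10 ms, rise 30 ms.

Default recording windows (trout 0.14 s, frogfish 0.065 s) bracket the
strike so neither the baseline nor the peak frame sits on a filter edge.
Cohorts draw one Gaussian vigor factor `1 + N(0, jitter)` per strike scaling
all amplitudes (joints covary across strikes, as repeated feeding events
do); the analysis drivers use jitter 0.30 (trout) and 0.20 (frogfish), which
reproduce cohort spreads of a few degrees (trout) and ~8–9° (frogfish).
Marker noise defaults to σ = 0.05 mm, inside the < 0.1 mm tracking-precision
regime of marker-based X-ray reconstruction.

Four markers per vertebra sit on the centrum (x ≈ ±0.45 L), the
neural-spine tip (y ≈ 1.8 L) and the ventral process (y ≈ −0.8 L). The
spread is chosen by the standard placement rule — maximise in-plane spread —
so that the analytic single-frame z-rotation noise floor, σ/√(Σ(x²+y²)) over
the centered constellation, stays at or below ~0.15° per bone at σ = 0.05 mm.
With zero-phase filtering (noise s.d. ×≈0.41 interior, ×≈0.53 at edges) the
recovered joint-delta error s.d. is ~0.13–0.15°, giving a ≳3.3σ margin
against the ±0.5° recovery requirement for the cranial joints, independent
of the seed. The smallest caudal centra (4–5 mm) bound their own markers'
spread; their deltas carry ~2× that noise, which is the physical limit of
4-bead tracking at that bone size, not an estimator deficiency.

### What the simulator does and does not emulate

It emulates chain topology and scale, sagittal strike programs with
realistic timing, initial curvature, whole-body drift, rigid bone-fixed
markers, tracking noise and dropout. It does **not** emulate soft-tissue
marker motion relative to bone (the real frogfish neurocranium markers sat
in soft tissue and the bones were rotoscoped), X-ray projection geometry,
calibration or undistortion error structure, dynamics (muscle, suction
loading), or lateral swimming motions. Passing the round-trip and robustness
tests therefore demonstrates the correctness and noise behaviour of the
measurement chain — not the accuracy of upstream 3-D reconstruction on real
video.

## Numerical choices

* Angles in degrees within (−180°, 180°]; distances mm; time s; frames are
  0-based with t = frame/rate.
* Pose matrices are validated to RᵀR = I and det R = +1 within 1e-9
  internally; files are accepted to 1e-6 and re-orthonormalised by SVD
  projection.
* CSV numerics are written with 17 significant digits, so file round trips
  are bit-exact; missing values are empty cells.
* Marker CSVs carry the frame rate in a `# frame_rate_hz=` comment so the
  rate survives a round trip.
* Pose sequences use world-from-bone convention, one row per frame, 16
  row-major values; an all-empty row is a gap.
* The per-strike baseline is frame 0; using onset instead is available but
  non-default (an onset-referenced baseline already contains ~5% of the
  signal by construction).
* End-to-end determinism: a fixed seed and configuration yield byte-identical
  numeric outputs; per-strike noise seeds derive from the cohort seed and
  strike index.

## Problem sizes used in validation

The shipped validation suite simulates full presets (26/19 bones, 66–71
frames), 20-replicate noisy frogfish cohorts, 100 random pose-fit instances
against a random-restart + simplex least-squares search oracle, and 10⁴
random rotations for the decompose/recompose identity. These sizes keep the
whole suite under a minute on one CPU while leaving the statistical margins
described above.

## Known limitations

* ACS placement on real data requires segmented bone geometry; the
  endplate-centroid construction is one defensible rule, and joint
  *translations* (not rotations) depend on the exact origin choice.
* The intrinsic z–y–x reading and the dorsal-positive sign flip are
  conventions; both are parameterised but results are only directly
  comparable across datasets using the same convention.
* Gap handling is conservative (no interpolation); long gaps shorten
  filterable segments and can leave unfiltered stubs.
* Cohort statistics are descriptive (mean ± s.e., max); no hypothesis
  testing across individuals or species is provided.
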