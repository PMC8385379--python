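"""Strike- and cohort-level kinematic analysis.

One *strike* (a feeding event) yields:

* a cranial-elevation trace — z rotation of the neurocranium-vs-body-plane
  JCS, re-zeroed to its initial value, with peak, onset and duration;
* per-joint dorsoventral rotation deltas at peak elevation, relative to the
  initial value (joint 1 = craniovertebral);
* a sagittal curvature profile — dorsoventral (y) translations of virtual
  landmarks on the neurocranium and each centrum, expressed in an ACS on the
  caudal-most vertebra — and its caudal-neighbour first difference
  ("translation per centrum").

Cohort summaries report mean, standard error (sample s.d. / sqrt(n) over
strikes), maximum and n. Strikes whose peak elevation is below the inclusion
threshold (default 5 deg, boundary inclusive) are excluded.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rigid import apply, inv_rigid
from .coordinate_systems import (AnatomicalCoordinateSystem,
                                 JointCoordinateSystem, JointKinematicsTrace,
                                 joint_trace)
from .errors import ConfigError, ParameterError, ValidationError
from .io_formats import ChainConfig, MarkerTrajectorySet, PoseMatrixSequence
from .rigid_body import RigidBodyDefinition, lowpass_filter_poses, pose_sequence

BODY_PLANE = "body_plane"

#: Onset definition: first frame where elevation exceeds this fraction of its
#: peak and stays above it for at least ``ONSET_HOLD_FRAMES`` frames.
ONSET_FRACTION = 0.05
ONSET_HOLD_FRAMES = 5


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class StrikeRecording:
    """Everything recorded (or simulated) for one feeding strike."""

    strike_id: str
    individual_id: str
    species: str
    frame_rate: float
    config: ChainConfig
    markers: MarkerTrajectorySet | None = None
    poses: dict[str, PoseMatrixSequence] = field(default_factory=dict)
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        counts = {seq.n_frames for seq in self.poses.values()}
        if self.markers is not None:
            counts.add(self.markers.n_frames)
        if len(counts) > 1:
            raise ValidationError(
                f"strike {self.strike_id}: sequences disagree on frame count {counts}"
            )

    @property
    def n_frames(self) -> int:
        if self.markers is not None:
            return self.markers.n_frames
        return next(iter(self.poses.values())).n_frames


@dataclass
class ElevationTrace:
    """Cranial elevation (deg, dorsal positive) relative to frame 0."""

    elevation: np.ndarray
    frame_rate: float
    peak_deg: float
    peak_frame: int
    onset_frame: int
    duration_ms: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.elevation)) / self.frame_rate


@dataclass
class CurvatureProfile:
    """Dorsoventral landmark translations in the caudal ACS frame at one frame.

    Position 0 is the neurocranium (craniovertebral-joint landmark), positions
    1..N the vertebral centra. ``y_rel_mm`` is baseline-subtracted (frame 0 by
    default); the caudal-most entry is identically zero since that vertebra
    carries the reference frame.
    """

    frame: int
    y_mm: np.ndarray
    y_rel_mm: np.ndarray

    @property
    def n_positions(self) -> int:
        return len(self.y_mm)


@dataclass
class CohortSummary:
    """Descriptive statistics of one quantity across strikes."""

    mean: float
    se: float
    max: float
    n: int
    single: bool = False


# ---------------------------------------------------------------------------
# Coordinate-system wiring from a chain config
# ---------------------------------------------------------------------------

def _identity_acs(bone: str) -> AnatomicalCoordinateSystem:
    return AnatomicalCoordinateSystem(bone, np.zeros(3), np.eye(3))


def joint_systems(cfg: ChainConfig) -> list[JointCoordinateSystem]:
    """JCSs for chain joints 1..N (sign-flipped so dorsal reads positive)."""
    out = []
    for k, cranial, caudal in cfg.joints():
        prox = cfg.bone(cranial).acs.get(k) or _identity_acs(cranial)
        dist = cfg.bone(caudal).acs.get(k) or _identity_acs(caudal)
        name = "craniovertebral" if k == 1 else f"intervertebral_{k - 1}"
        out.append(JointCoordinateSystem(k, prox, dist, sign_flip_z=True,
                                         name=name))
    return out


def elevation_system(cfg: ChainConfig) -> JointCoordinateSystem:
    """Cranial-elevation JCS: body plane (proximal) vs neurocranium (distal),
    no sign flip — positive z is elevation directly."""
    if cfg.body_plane is None:
        raise ConfigError("config has no body plane; cannot measure elevation")
    prox = cfg.body_plane.acs or _identity_acs(BODY_PLANE)
    neuro = cfg.bones[0]
    dist = neuro.acs.get(1) or _identity_acs(neuro.name)
    return JointCoordinateSystem(0, prox, dist, sign_flip_z=False,
                                 name="cranial_elevation")


# ---------------------------------------------------------------------------
# Pose recovery and filtering
# ---------------------------------------------------------------------------

def recover_poses(mset: MarkerTrajectorySet, cfg: ChainConfig,
                  external_poses: dict[str, PoseMatrixSequence] | None = None
                  ) -> dict[str, PoseMatrixSequence]:
    """Fit world poses for every bone (and the body plane) from markers.

    Bones without at least three markers in the trajectory set (e.g.
    rotoscoped bones) must be supplied through ``external_poses``.
    """
    external_poses = external_poses or {}
    out: dict[str, PoseMatrixSequence] = {}
    specs = [(b.name, b.markers) for b in cfg.bones]
    if cfg.body_plane is not None:
        specs.append((BODY_PLANE, cfg.body_plane.markers))
    for name, markers in specs:
        usable = {m: p for m, p in markers.items() if m in mset.markers}
        if len(usable) >= 3:
            defn = RigidBodyDefinition(bone_name=name, markers=usable)
            out[name], _ = pose_sequence(mset, defn)
        elif name in external_poses:
            out[name] = external_poses[name]
        else:
            raise ConfigError(
                f"bone {name!r}: fewer than 3 markers tracked and no external "
                f"pose sequence supplied"
            )
    return out


def filter_poses(poses: dict[str, PoseMatrixSequence], cfg: ChainConfig
                 ) -> dict[str, PoseMatrixSequence]:
    return {name: lowpass_filter_poses(seq, cfg.filter_cutoff_hz,
                                       cfg.frame_rate, order=cfg.filter_order)
            for name, seq in poses.items()}


# ---------------------------------------------------------------------------
# Strike-level measures
# ---------------------------------------------------------------------------

def _onset_frame(elev: np.ndarray, peak: float,
                 fraction: float = ONSET_FRACTION,
                 hold: int = ONSET_HOLD_FRAMES) -> int:
    if not peak > 0:
        return 0
    above = elev > fraction * peak
    n = len(above)
    for i in range(n):
        stop = min(i + hold, n)
        if above[i:stop].all() and stop > i:
            return i
    return int(np.nanargmax(elev))


def elevation_trace_from_poses(poses: dict[str, PoseMatrixSequence],
                               cfg: ChainConfig) -> ElevationTrace:
    """Cranial elevation from neurocranium and body-plane pose sequences."""
    neuro = cfg.bones[0].name
    if BODY_PLANE not in poses:
        raise ConfigError("no body-plane pose sequence; cannot measure elevation")
    trace = joint_trace(poses[BODY_PLANE], poses[neuro], elevation_system(cfg))
    rz = trace.rot_z
    valid = np.nonzero(~np.isnan(rz))[0]
    if valid.size == 0:
        raise ValidationError("elevation trace has no valid frames")
    elev = rz - rz[valid[0]]
    peak_frame = int(np.nanargmax(elev))
    peak = float(elev[peak_frame])
    onset = _onset_frame(elev, peak)
    duration_ms = (peak_frame - onset) / cfg.frame_rate * 1000.0
    return ElevationTrace(elevation=elev, frame_rate=cfg.frame_rate,
                          peak_deg=peak, peak_frame=peak_frame,
                          onset_frame=onset, duration_ms=duration_ms)


def elevation_trace(strike: StrikeRecording, use_markers: bool = False,
                    filtering: bool = False) -> ElevationTrace:
    """Convenience wrapper measuring elevation on a strike recording."""
    poses = _strike_poses(strike, use_markers, filtering)
    return elevation_trace_from_poses(poses, strike.config)


def include_strike(trace: ElevationTrace, threshold: float = 5.0) -> bool:
    """Inclusion rule: peak cranial elevation of at least ``threshold`` deg."""
    return bool(trace.peak_deg >= threshold)


def joint_rotation_deltas_at_peak(traces: list[JointKinematicsTrace],
                                  peak_frame: int,
                                  baseline_frame: int = 0) -> np.ndarray:
    """Per-joint dorsoventral rotation delta (deg) at peak cranial elevation,
    relative to the initial value. NaN where either frame is a gap."""
    out = np.full(len(traces), np.nan)
    for i, tr in enumerate(traces):
        a = tr.rot_z[baseline_frame]
        b = tr.rot_z[peak_frame]
        if not (np.isnan(a) or np.isnan(b)):
            out[i] = b - a
    return out


def _landmarks(cfg: ChainConfig) -> list[tuple[str, np.ndarray]]:
    """(bone, bone-frame point) per profile position 0..N."""
    out = []
    neuro = cfg.bones[0]
    if 1 in neuro.acs:  # craniovertebral-joint landmark
        out.append((neuro.name, neuro.acs[1].origin))
    else:
        out.append((neuro.name, neuro.centrum if neuro.centrum is not None
                    else np.zeros(3)))
    for b in cfg.bones[1:]:
        out.append((b.name, b.centrum if b.centrum is not None else np.zeros(3)))
    return out


def curvature_profile(poses: dict[str, PoseMatrixSequence], cfg: ChainConfig,
                      frame: int, baseline_frame: int = 0) -> CurvatureProfile:
    """Dorsoventral landmark translations in the caudal ACS at one frame."""
    caudal = cfg.caudal_acs()
    base_name = cfg.bones[-1].name
    y = np.full(cfg.n_vertebrae + 1, np.nan)
    y0 = np.full(cfg.n_vertebrae + 1, np.nan)
    for f, dest in ((frame, y), (baseline_frame, y0)):
        Wc = poses[base_name].transforms[f] @ caudal.to_matrix()
        if np.isnan(Wc).any():
            continue
        Winv = inv_rigid(Wc)
        for pos, (bone, point) in enumerate(_landmarks(cfg)):
            Wb = poses[bone].transforms[f]
            if np.isnan(Wb).any():
                continue
            dest[pos] = (Winv @ Wb @ np.append(point, 1.0))[1]
    return CurvatureProfile(frame=frame, y_mm=y, y_rel_mm=y - y0)


def per_centrum_translation(profile: CurvatureProfile) -> np.ndarray:
    """Caudal-neighbour first difference of the baseline-subtracted profile:
    ``delta_y(k) = y(k) - y(k+1)`` (position 0 = neurocranium vs vertebra 1)."""
    if profile.n_positions < 2:
        raise ParameterError("profile needs at least two positions")
    return profile.y_rel_mm[:-1] - profile.y_rel_mm[1:]


# ---------------------------------------------------------------------------
# Cohort-level measures
# ---------------------------------------------------------------------------

def cohort_summary(values) -> CohortSummary:
    """Mean, standard error, maximum and n of a set of per-strike values."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    n = len(v)
    if n == 0:
        raise ParameterError("cohort summary of an empty value set")
    if n == 1:
        return CohortSummary(mean=float(v[0]), se=0.0, max=float(v[0]), n=1,
                             single=True)
    return CohortSummary(mean=float(v.mean()),
                         se=float(v.std(ddof=1) / np.sqrt(n)),
                         max=float(v.max()), n=n)


def mean_trace(traces: list[ElevationTrace], align: str = "onset"
               ) -> tuple[np.ndarray, np.ndarray]:
    """Across-strike mean elevation at every aligned time step.

    Traces are aligned at onset (default) or peak; the mean is taken over
    strikes present at each step and steps covered by fewer than two strikes
    are dropped. Returns (times_s relative to the alignment event, mean_deg).
    """
    if len(traces) < 2:
        raise ParameterError("mean trace needs at least two strikes")
    if align not in ("onset", "peak"):
        raise ParameterError(f"unknown alignment {align!r}")
    rate = traces[0].frame_rate
    anchors = [tr.onset_frame if align == "onset" else tr.peak_frame
               for tr in traces]
    lo = min(-a for a in anchors)
    hi = max(len(tr.elevation) - a for tr, a in zip(traces, anchors))
    grid = np.arange(lo, hi)
    total = np.zeros(len(grid))
    count = np.zeros(len(grid), dtype=int)
    for tr, a in zip(traces, anchors):
        offs = np.arange(len(tr.elevation)) - a
        ok = ~np.isnan(tr.elevation)
        idx = offs[ok] - lo
        total[idx] += tr.elevation[ok]
        count[idx] += 1
    keep = count >= 2
    return grid[keep] / rate, total[keep] / count[keep]


# ---------------------------------------------------------------------------
# Whole-strike / whole-cohort drivers
# ---------------------------------------------------------------------------

@dataclass
class StrikeAnalysis:
    """All per-strike outputs of the pipeline."""

    strike_id: str
    individual_id: str
    included: bool
    elevation: ElevationTrace
    joint_traces: list[JointKinematicsTrace]
    deltas_deg: np.ndarray
    curvature_peak: CurvatureProfile
    per_centrum_mm: np.ndarray
    frame_rate: float


def _strike_poses(strike: StrikeRecording, use_markers: bool,
                  filtering: bool) -> dict[str, PoseMatrixSequence]:
    if use_markers:
        if strike.markers is None:
            raise ConfigError(f"strike {strike.strike_id} carries no markers")
        poses = recover_poses(strike.markers, strike.config,
                              external_poses=strike.poses)
    else:
        poses = strike.poses
    if filtering:
        poses = filter_poses(poses, strike.config)
    return poses


def analyze_strike(strike: StrikeRecording, use_markers: bool = True,
                   filtering: bool = True,
                   threshold: float | None = None) -> StrikeAnalysis:
    """Run the full single-strike pipeline: pose recovery, optional zero-phase
    filtering, elevation, joint deltas at peak and the curvature profile."""
    cfg = strike.config
    poses = _strike_poses(strike, use_markers, filtering)
    elev = elevation_trace_from_poses(poses, cfg)
    jtraces = []
    for jcs in joint_systems(cfg):
        _, cranial, caudal = next(j for j in cfg.joints() if j[0] == jcs.joint_index)
        jtraces.append(joint_trace(poses[cranial], poses[caudal], jcs))
    deltas = joint_rotation_deltas_at_peak(jtraces, elev.peak_frame)
    prof = curvature_profile(poses, cfg, elev.peak_frame)
    thr = cfg.elevation_threshold_deg if threshold is None else threshold
    return StrikeAnalysis(
        strike_id=strike.strike_id, individual_id=strike.individual_id,
        included=include_strike(elev, thr), elevation=elev,
        joint_traces=jtraces, deltas_deg=deltas, curvature_peak=prof,
        per_centrum_mm=per_centrum_translation(prof), frame_rate=cfg.frame_rate,
    )


@dataclass
class CohortResult:
    """Included/excluded strikes plus cohort-level descriptive statistics."""

    analyses: list[StrikeAnalysis]
    excluded: list[tuple[str, str]]
    peak_elevation: CohortSummary | None
    joint_delta_summaries: list[CohortSummary | None]
    mean_elevation: tuple[np.ndarray, np.ndarray] | None

    @property
    def included(self) -> list[StrikeAnalysis]:
        return [a for a in self.analyses if a.included]


def analyze_cohort(strikes: list[StrikeRecording], use_markers: bool = True,
                   filtering: bool = True,
                   threshold: float | None = None) -> CohortResult:
    analyses = [analyze_strike(s, use_markers=use_markers, filtering=filtering,
                               threshold=threshold) for s in strikes]
    included = [a for a in analyses if a.included]
    excluded = [(a.strike_id,
                 f"peak elevation {a.elevation.peak_deg:.2f} deg below threshold")
                for a in analyses if not a.included]
    if included:
        peaks = cohort_summary([a.elevation.peak_deg for a in included])
        n_joints = len(included[0].deltas_deg)
        joint_summaries: list[CohortSummary | None] = []
        for k in range(n_joints):
            vals = np.array([a.deltas_deg[k] for a in included])
            joint_summaries.append(cohort_summary(vals)
                                   if np.isfinite(vals).any() else None)
        mt = (mean_trace([a.elevation for a in included])
              if len(included) >= 2 else None)
    else:
        peaks, joint_summaries, mt = None, [], None
    return CohortResult(analyses=analyses, excluded=excluded,
                        peak_elevation=peaks,
                        joint_delta_summaries=joint_summaries,
                        mean_elevation=mt)


# ---------------------------------------------------------------------------
# Long-format table export
# ---------------------------------------------------------------------------

def elevation_table(analyses: list[StrikeAnalysis]) -> pd.DataFrame:
    rows = []
    for a in analyses:
        for f, v in enumerate(a.elevation.elevation):
            rows.append((a.strike_id, f, f / a.frame_rate, v))
    return pd.DataFrame(rows, columns=["strike", "frame", "time_s",
                                       "elevation_deg"])


def joint_delta_table(analyses: list[StrikeAnalysis]) -> pd.DataFrame:
    rows = []
    for a in analyses:
        for k, v in enumerate(a.deltas_deg, start=1):
            rows.append((a.strike_id, k, v))
    return pd.DataFrame(rows, columns=["strike", "joint", "delta_rot_z_deg"])


def curvature_table(analyses: list[StrikeAnalysis]) -> pd.DataFrame:
    rows = []
    for a in analyses:
        for pos, v in enumerate(a.curvature_peak.y_rel_mm):
            rows.append((a.strike_id, pos, v))
    return pd.DataFrame(rows, columns=["strike", "position", "y_rel_mm"])


def summary_table(result: CohortResult) -> pd.DataFrame:
    rows = []
    if result.peak_elevation is not None:
        s = result.peak_elevation
        rows.append(("peak_elevation_deg", s.mean, s.se, s.max, s.n))
    for k, s in enumerate(result.joint_delta_summaries, start=1):
        if s is not None:
            rows.append((f"joint_{k}_delta_rot_z_deg", s.mean, s.se, s.max, s.n))
    return pd.DataFrame(rows, columns=["quantity", "mean", "se", "max", "n"])
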