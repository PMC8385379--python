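"""Rigid-body pose estimation from bone-fixed markers, tracking precision and
zero-phase low-pass filtering of pose sequences.

Pose fitting is the closed-form least-squares superposition (Kabsch/orthogonal
Procrustes with the determinant correction that enforces a proper rotation):
given reference marker positions in the bone frame and observed world
positions, the fitted pose minimises the sum of squared marker residuals over
all rigid transforms.

Tracking precision follows the standard marker-based XROMM metric: for every
unordered pair of markers, take the standard deviation over frames of their
inter-marker distance, then average over pairs. Rigid, noise-free motion gives
exactly zero; for two markers whose coordinates carry independent isotropic
Gaussian noise of s.d. sigma per axis, the statistic converges to
``sigma * sqrt(2)``.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

from ._rigid import hom
from .errors import (DegenerateGeometryError, InsufficientMarkersError,
                     ParameterError, ValidationError)
from .io_formats import MarkerTrajectorySet, PoseMatrixSequence

#: Second singular value of centered marker positions must exceed this (mm)
#: for the geometry to be usably non-collinear.
COLLINEARITY_TOL_MM = 1e-6


@dataclass
class RigidBodyDefinition:
    """Reference marker constellation of one bone (bone frame, mm, from CT)."""

    bone_name: str
    markers: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.markers = {k: np.asarray(v, dtype=float) for k, v in self.markers.items()}
        _check_geometry(self.bone_name, np.array(list(self.markers.values())))

    @property
    def names(self) -> list[str]:
        return list(self.markers.keys())


def _check_geometry(bone_name: str, pts: np.ndarray) -> None:
    if len(pts) < 3:
        raise InsufficientMarkersError(
            f"{bone_name}: need >= 3 markers, got {len(pts)}"
        )
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    # collinear constellations have (at most) one non-trivial singular value;
    # coplanar sets (e.g. a midsagittal body plane) are fine for pose fitting
    if sv[1] <= COLLINEARITY_TOL_MM:
        raise DegenerateGeometryError(
            f"{bone_name}: marker constellation is collinear "
            f"(second singular value {sv[1]:.3g} mm)"
        )


@dataclass
class PoseFitResult:
    """Fitted world-from-bone pose plus its marker residual."""

    pose: np.ndarray
    rmse: float
    n_markers_used: int


def fit_rigid_pose(definition: RigidBodyDefinition,
                   observed: dict[str, np.ndarray]) -> PoseFitResult:
    """Least-squares rigid pose from observed world marker positions.

    Markers are matched to the definition by name; observations that are
    absent or NaN are dropped. At least three non-collinear common markers are
    required.
    """
    names = [n for n in definition.names
             if n in observed and not np.isnan(np.asarray(observed[n])).any()]
    if len(names) < 3:
        raise InsufficientMarkersError(
            f"{definition.bone_name}: only {len(names)} usable common markers"
        )
    X = np.array([definition.markers[n] for n in names])   # bone frame
    Y = np.array([np.asarray(observed[n], float) for n in names])  # world
    _check_geometry(definition.bone_name, X)
    R, t = _kabsch(X, Y)
    resid = (X @ R.T + t) - Y
    rmse = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return PoseFitResult(pose=hom(R, t), rmse=rmse, n_markers_used=len(names))


def _kabsch(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proper rotation R and translation t minimising ||R X + t - Y||^2."""
    xm = X.mean(axis=0)
    ym = Y.mean(axis=0)
    H = (X - xm).T @ (Y - ym)
    U, _, Vt = np.linalg.svd(H)
    D = np.eye(3)
    D[2, 2] = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ D @ U.T
    return R, ym - R @ xm


def pose_sequence(mset: MarkerTrajectorySet,
                  definition: RigidBodyDefinition
                  ) -> tuple[PoseMatrixSequence, np.ndarray]:
    """Per-frame pose fits for one bone; frames with < 3 usable markers are
    gaps. Returns the pose sequence and the per-frame fit RMSE (NaN at gaps).
    """
    names = [n for n in definition.names if n in mset.markers]
    idx = [mset.index(n) for n in names]
    n = mset.n_frames
    T = np.full((n, 4, 4), np.nan)
    rmse = np.full(n, np.nan)
    any_ok = False
    for i in range(n):
        obs = {name: mset.positions[i, j] for name, j in zip(names, idx)}
        try:
            fit = fit_rigid_pose(definition, obs)
        except (InsufficientMarkersError, DegenerateGeometryError):
            continue
        T[i] = fit.pose
        rmse[i] = fit.rmse
        any_ok = True
    if not any_ok:
        raise ValidationError(
            f"{definition.bone_name}: no frame has enough markers for a pose"
        )
    return PoseMatrixSequence(bone_name=definition.bone_name, transforms=T), rmse


def tracking_precision(mset: MarkerTrajectorySet,
                       marker_subset: list[str] | None = None) -> float:
    """Mean over marker pairs of the s.d. over frames of inter-marker distance.

    Sample standard deviation (n-1 denominator); pairs need at least two
    frames with both markers present.
    """
    names = marker_subset if marker_subset is not None else mset.markers
    if len(names) < 2:
        raise ParameterError("tracking precision needs at least two markers")
    sds = []
    for a, b in itertools.combinations(names, 2):
        pa = mset.get(a)
        pb = mset.get(b)
        ok = ~(np.isnan(pa).any(axis=1) | np.isnan(pb).any(axis=1))
        if ok.sum() < 2:
            continue
        d = np.linalg.norm(pa[ok] - pb[ok], axis=1)
        sds.append(np.std(d, ddof=1))
    if not sds:
        raise ValidationError("no marker pair has two frames of common data")
    return float(np.mean(sds))


# ---------------------------------------------------------------------------
# Zero-phase pose filtering
# ---------------------------------------------------------------------------

def lowpass_filter_poses(seq: PoseMatrixSequence, cutoff: float,
                         frame_rate: float, order: int = 2) -> PoseMatrixSequence:
    """Zero-phase Butterworth low-pass of a pose sequence.

    The six pose parameters — three translations and the rotation as a unit
    quaternion with sign continuity enforced — are filtered forward and
    backward with a Butterworth of the given order (effective order doubled,
    zero lag), then the quaternions are renormalised. Gaps split the sequence
    into independently filtered segments; segments shorter than three times
    the filter order pass through unfiltered with a warning. Edge padding is
    by reflection of length three times the order.
    """
    if not 0 < cutoff < frame_rate / 2:
        raise ParameterError(
            f"cutoff {cutoff} Hz must lie in (0, Nyquist={frame_rate / 2} Hz)"
        )
    b, a = butter(order, cutoff / (frame_rate / 2.0), btype="low")
    padlen = 3 * order
    out = np.full_like(seq.transforms, np.nan)
    for start, stop in seq.segments():
        block = seq.transforms[start:stop]
        n = stop - start
        if n <= padlen:
            if n > 1:
                warnings.warn(
                    f"{seq.bone_name}: segment [{start}, {stop}) too short to "
                    f"filter (n={n}); passed through unfiltered"
                )
            out[start:stop] = block
            continue
        t = block[:, :3, 3]
        quat = Rotation.from_matrix(block[:, :3, :3]).as_quat()
        for i in range(1, n):  # hemisphere continuity
            if np.dot(quat[i], quat[i - 1]) < 0:
                quat[i] = -quat[i]
        tf = filtfilt(b, a, t, axis=0, padtype="even", padlen=padlen)
        qf = filtfilt(b, a, quat, axis=0, padtype="even", padlen=padlen)
        qf /= np.linalg.norm(qf, axis=1, keepdims=True)
        Rf = Rotation.from_quat(qf).as_matrix()
        out[start:stop, :3, :3] = Rf
        out[start:stop, :3, 3] = tf
        out[start:stop, 3, :] = [0.0, 0.0, 0.0, 1.0]
    return PoseMatrixSequence(bone_name=seq.bone_name, transforms=out,
                              atol=1e-8)
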