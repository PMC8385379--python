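"""Anatomical and joint coordinate systems.

Axis semantics follow the standard fish-kinematics convention: within an
anatomical coordinate system (ACS), +x points cranially (craniocaudal axis),
+y dorsally (dorsoventral axis) and +z to the animal's left (lateral axis);
the frame is right-handed. A joint coordinate system (JCS) pairs two ACSs, one
on the cranial bone (proximal) and one on the caudal bone (distal), placed so
they coincide in the reference (CT) pose — every joint degree of freedom is
zero at reference by construction.

Rotations are decomposed in intrinsic z-y-x order, ``R = Rz(g) Ry(b) Rx(a)``:
``g`` is dorsoventral rotation in the sagittal plane, ``b`` lateral rotation,
``a`` axial roll. The raw z angle of "caudal bone relative to its cranial
neighbour" is negative for dorsal (extension) motion, so intervertebral traces
are sign-flipped (``sign_flip_z=True``) to make dorsal rotation positive. The
cranial-elevation JCS (neurocranium relative to the body plane) needs no flip:
positive z is elevation directly.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from ._rigid import apply, inv_rigid, hom
from .errors import AlignmentError, DegenerateGeometryError, ValidationError

#: |beta| above which a frame is flagged as close to gimbal lock (deg).
GIMBAL_BAND_DEG = 89.5


@dataclass
class AnatomicalCoordinateSystem:
    """A bone-fixed anatomical frame.

    ``origin`` (mm) and ``orientation`` (3x3, columns = x, y, z axes) are
    expressed in the bone's reference frame.
    """

    bone_name: str
    origin: np.ndarray
    orientation: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        R = self.orientation
        if (np.max(np.abs(R.T @ R - np.eye(3))) > 1e-8
                or abs(np.linalg.det(R) - 1.0) > 1e-8):
            raise ValidationError(
                f"ACS orientation on {self.bone_name!r} is not a proper rotation"
            )

    def to_matrix(self) -> np.ndarray:
        """Bone-from-ACS homogeneous transform."""
        return hom(self.orientation, self.origin)


def build_acs(bone_name: str, cranial_centroid, caudal_centroid,
              dorsal_landmark) -> AnatomicalCoordinateSystem:
    """Construct an ACS from centrum endplate centroids and a dorsal landmark.

    Origin is the centrum centroid (midpoint of the endplate centroids); +x
    runs caudal-to-cranial endplate centroid; +y is the component of
    (dorsal landmark - origin) orthogonal to x; z = x cross y.
    """
    cr = np.asarray(cranial_centroid, dtype=float)
    ca = np.asarray(caudal_centroid, dtype=float)
    dl = np.asarray(dorsal_landmark, dtype=float)
    origin = 0.5 * (cr + ca)
    x = cr - ca
    nx = np.linalg.norm(x)
    if nx < 1e-12:
        raise DegenerateGeometryError(f"{bone_name}: endplate centroids coincide")
    x = x / nx
    y = dl - origin
    y = y - (y @ x) * x
    ny = np.linalg.norm(y)
    if ny < 1e-9:
        raise DegenerateGeometryError(
            f"{bone_name}: dorsal landmark collinear with centrum axis"
        )
    y = y / ny
    z = np.cross(x, y)
    return AnatomicalCoordinateSystem(bone_name, origin, np.column_stack([x, y, z]))


@dataclass
class JointCoordinateSystem:
    """A pair of coincident-at-reference ACSs defining one joint.

    ``sign_flip_z=True`` for chain (craniovertebral and intervertebral) joints,
    where the measured z rotation of the caudal bone relative to its cranial
    neighbour is multiplied by -1 so dorsal rotation reads positive.
    """

    joint_index: int
    proximal: AnatomicalCoordinateSystem  # on the cranial bone
    distal: AnatomicalCoordinateSystem    # on the caudal bone
    sign_flip_z: bool = True
    name: str = ""


@dataclass
class JointKinematicsTrace:
    """Six per-frame degrees of freedom for one joint.

    Rotations in degrees (``rot_z`` dorsoventral with dorsal positive,
    ``rot_y`` lateral, ``rot_x`` axial), translations in mm of the distal ACS
    origin expressed in the proximal ACS frame. Gap frames are NaN;
    ``gimbal_flag`` marks frames within half a degree of gimbal lock.
    """

    joint_index: int
    rot_z: np.ndarray
    rot_y: np.ndarray
    rot_x: np.ndarray
    trans_x: np.ndarray
    trans_y: np.ndarray
    trans_z: np.ndarray
    gimbal_flag: np.ndarray = field(default=None)  # type: ignore[assignment]
    name: str = ""

    def __post_init__(self) -> None:
        if self.gimbal_flag is None:
            self.gimbal_flag = np.zeros(len(self.rot_z), dtype=bool)

    @property
    def n_frames(self) -> int:
        return len(self.rot_z)

    @property
    def is_gap(self) -> np.ndarray:
        return np.isnan(self.rot_z)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"rot_z": self.rot_z, "rot_y": self.rot_y, "rot_x": self.rot_x,
                "trans_x": self.trans_x, "trans_y": self.trans_y,
                "trans_z": self.trans_z}


def _decompose_matrices(T: np.ndarray, sign_flip_z: bool):
    """Vectorised z-y-x decomposition of relative transforms (n, 4, 4)."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Gimbal lock")
        ang = Rotation.from_matrix(T[:, :3, :3]).as_euler("ZYX", degrees=True)
    if ang.ndim == 1:
        ang = ang[None, :]
    gamma, beta, alpha = ang[:, 0], ang[:, 1], ang[:, 2]
    rot_z = -gamma if sign_flip_z else gamma
    gimbal = np.abs(beta) >= GIMBAL_BAND_DEG
    t = T[:, :3, 3]
    return rot_z, beta, alpha, t, gimbal


def jcs_decompose(world_from_proximal_acs: np.ndarray,
                  world_from_distal_acs: np.ndarray,
                  sign_flip_z: bool = True) -> dict[str, float]:
    """Decompose one frame of relative joint motion.

    Returns ``rot_z``/``rot_y``/``rot_x`` (deg), ``trans_x/y/z`` (mm) and a
    ``gimbal_flag``; the relative transform is
    ``inv(world_from_proximal_acs) @ world_from_distal_acs``.
    """
    T = inv_rigid(np.asarray(world_from_proximal_acs, float)) @ np.asarray(
        world_from_distal_acs, float)
    rot_z, beta, alpha, t, gimbal = _decompose_matrices(T[None], sign_flip_z)
    return {"rot_z": float(rot_z[0]), "rot_y": float(beta[0]),
            "rot_x": float(alpha[0]), "trans_x": float(t[0, 0]),
            "trans_y": float(t[0, 1]), "trans_z": float(t[0, 2]),
            "gimbal_flag": bool(gimbal[0])}


def joint_trace(proximal_poses, distal_poses,
                jcs: JointCoordinateSystem) -> JointKinematicsTrace:
    """Per-frame JCS decomposition along two aligned pose sequences.

    A gap in either bone propagates to the trace at that frame.
    """
    if proximal_poses.n_frames != distal_poses.n_frames:
        raise AlignmentError(
            f"joint {jcs.joint_index}: frame counts differ "
            f"({proximal_poses.n_frames} vs {distal_poses.n_frames})"
        )
    n = proximal_poses.n_frames
    Cp = jcs.proximal.to_matrix()
    Cd = jcs.distal.to_matrix()
    ok = ~(proximal_poses.is_gap | distal_poses.is_gap)
    out = {k: np.full(n, np.nan) for k in
           ("rot_z", "rot_y", "rot_x", "trans_x", "trans_y", "trans_z")}
    gimbal = np.zeros(n, dtype=bool)
    if ok.any():
        Wp = proximal_poses.transforms[ok] @ Cp
        Wd = distal_poses.transforms[ok] @ Cd
        T = inv_rigid(Wp) @ Wd
        rot_z, beta, alpha, t, gflags = _decompose_matrices(T, jcs.sign_flip_z)
        out["rot_z"][ok] = rot_z
        out["rot_y"][ok] = beta
        out["rot_x"][ok] = alpha
        out["trans_x"][ok] = t[:, 0]
        out["trans_y"][ok] = t[:, 1]
        out["trans_z"][ok] = t[:, 2]
        gimbal[ok] = gflags
    return JointKinematicsTrace(joint_index=jcs.joint_index, name=jcs.name,
                                gimbal_flag=gimbal, **out)


def virtual_landmark_trajectory(point, bone_poses, reference_acs,
                                reference_poses) -> np.ndarray:
    """Trajectory of a bone-fixed virtual landmark in a reference ACS frame.

    ``p_ref(t) = inv(world_from_reference_acs(t)) @ world_from_bone(t) @ point``.
    Returns (n_frames, 3) with NaN rows where either pose is a gap.
    """
    if bone_poses.n_frames != reference_poses.n_frames:
        raise AlignmentError("bone and reference pose sequences differ in length")
    p = np.asarray(point, dtype=float)
    n = bone_poses.n_frames
    out = np.full((n, 3), np.nan)
    ok = ~(bone_poses.is_gap | reference_poses.is_gap)
    if ok.any():
        Wref = reference_poses.transforms[ok] @ reference_acs.to_matrix()
        p_world = apply(bone_poses.transforms[ok], p)
        out[ok] = apply(inv_rigid(Wref), p_world)
    return out
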