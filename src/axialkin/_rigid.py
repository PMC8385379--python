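"""Small helpers for 4x4 homogeneous rigid transforms.

Convention used throughout the package: a pose matrix is *world-from-bone*,
i.e. it maps coordinates expressed in the bone's reference frame into world
coordinates. Units are millimetres.
"""
from __future__ import annotations

import numpy as np

RIGID_ATOL = 1e-9


def hom(R: np.ndarray | None = None, t: np.ndarray | None = None) -> np.ndarray:
    """Assemble a 4x4 homogeneous transform from rotation and translation."""
    T = np.eye(4)
    if R is not None:
        T[:3, :3] = R
    if t is not None:
        T[:3, 3] = t
    return T


def rot(T: np.ndarray) -> np.ndarray:
    return T[..., :3, :3]


def trans(T: np.ndarray) -> np.ndarray:
    return T[..., :3, 3]


def inv_rigid(T: np.ndarray) -> np.ndarray:
    """Invert rigid transform(s) without a general matrix inverse."""
    R = T[..., :3, :3]
    t = T[..., :3, 3]
    out = np.zeros_like(T)
    Rt = np.swapaxes(R, -1, -2)
    out[..., :3, :3] = Rt
    out[..., :3, 3] = -np.einsum("...ij,...j->...i", Rt, t)
    out[..., 3, 3] = 1.0
    return out


def apply(T: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Apply rigid transform(s) to 3-vector(s)."""
    return np.einsum("...ij,...j->...i", T[..., :3, :3], p) + T[..., :3, 3]


def rigidity_error(T: np.ndarray) -> float:
    """Max deviation of R from a proper rotation and of the last row from (0,0,0,1)."""
    R = T[:3, :3]
    err = np.max(np.abs(R.T @ R - np.eye(3)))
    err = max(err, abs(np.linalg.det(R) - 1.0))
    err = max(err, np.max(np.abs(T[3] - np.array([0.0, 0.0, 0.0, 1.0]))))
    return float(err)


def is_rigid(T: np.ndarray, atol: float = RIGID_ATOL) -> bool:
    return rigidity_error(T) <= atol


def nearest_rotation(R: np.ndarray) -> np.ndarray:
    """Project a near-rotation matrix onto SO(3) (proper rotation) via SVD."""
    U, _, Vt = np.linalg.svd(R)
    D = np.eye(3)
    D[2, 2] = np.sign(np.linalg.det(U @ Vt))
    return U @ D @ Vt


def rotation_about_point(R: np.ndarray, point: np.ndarray) -> np.ndarray:
    """Rigid transform rotating by R about a fixed point."""
    p = np.asarray(point, dtype=float)
    return hom(R, p - R @ p)
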