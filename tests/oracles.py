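"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the pose-fit oracle is a
random-restart search over rotation parameters with simplex refinement (no
SVD), and the recomposition oracle rebuilds rotation matrices from decomposed
angles by explicit axis-rotation products.
"""
from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def pose_objective(rotvec: np.ndarray, X: np.ndarray, Y: np.ndarray) -> float:
    """Sum of squared residuals for the best translation given a rotation."""
    R = Rotation.from_rotvec(rotvec).as_matrix()
    XR = X @ R.T
    t = Y.mean(axis=0) - XR.mean(axis=0)
    return float(np.sum((XR + t - Y) ** 2))


def brute_force_pose_objective(X: np.ndarray, Y: np.ndarray, rng,
                               n_starts: int = 200) -> float:
    """Least-squares superposition objective by dense random search over
    rotation vectors plus Nelder-Mead refinement of the best candidates."""
    starts = rng.normal(size=(n_starts, 3)) * rng.uniform(
        0.1, np.pi, size=(n_starts, 1))
    vals = np.array([pose_objective(v, X, Y) for v in starts])
    best = np.inf
    for idx in np.argsort(vals)[:3]:
        res = minimize(pose_objective, starts[idx], args=(X, Y),
                       method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14,
                                "maxiter": 2000})
        best = min(best, float(res.fun))
    return best


def rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rot_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def recompose_zyx(gamma_deg: float, beta_deg: float, alpha_deg: float
                  ) -> np.ndarray:
    """Intrinsic z-y-x recomposition Rz(gamma) @ Ry(beta) @ Rx(alpha)."""
    return rot_z(gamma_deg) @ rot_y(beta_deg) @ rot_x(alpha_deg)
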