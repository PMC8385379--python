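"""Forward-kinematics simulator of cranio-vertebral chains.

Generates marker trajectories plus noise-free ground-truth poses for
trout-like and frogfish-like feeding strikes, standing in for X-ray
recordings. The chain is an ordered series of rigid bones — neurocranium,
then vertebra 1..N — connected by revolute-plus joints; the caudal-most
vertebra is the fixed base (whole-body motion can be superimposed). Joint
angles are programmed as smoothstep ramps; programmed values are expressed in
the measurement convention (z dorsal-positive), so a noise-free simulation
followed by the analysis pipeline reproduces the programs exactly.

Preset geometry is a qualitative emulation of the two study species: trout —
25 modelled vertebrae of uniform, small centra, 500 fps, midsagittal
body-plane markers, whole-body translation during the strike; frogfish — 18
vertebrae with centra graded larger cranially, an initial S-curved column
(cranial joints flexed, mid-caudal joints extended), 1000 fps, bilateral
body-plane markers, body held stationary.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from ._rigid import hom, inv_rigid
from .axial_pipeline import BODY_PLANE, StrikeRecording
from .coordinate_systems import AnatomicalCoordinateSystem
from .errors import ParameterError
from .io_formats import (BodyPlaneSpec, BoneSpec, ChainConfig,
                         MarkerTrajectorySet, PoseMatrixSequence)

NEUROCRANIUM = "neurocranium"


# ---------------------------------------------------------------------------
# Programs and noise
# ---------------------------------------------------------------------------

@dataclass
class JointRamp:
    """Smoothstep ramp of one joint's rotation (deg), in the measurement
    convention (z dorsal-positive)."""

    amp_z: float
    amp_y: float = 0.0
    amp_x: float = 0.0
    onset_s: float = 0.0
    rise_s: float = 0.02
    shape: str = "smoothstep"

    def angles(self, t: np.ndarray) -> np.ndarray:
        """(len(t), 3) programmed z, y, x angles in degrees."""
        if self.shape != "smoothstep":
            raise ParameterError(f"unknown ramp shape {self.shape!r}")
        u = np.clip((t - self.onset_s) / self.rise_s, 0.0, 1.0)
        s = u * u * (3.0 - 2.0 * u)
        return np.outer(s, [self.amp_z, self.amp_y, self.amp_x])


@dataclass
class JointProgram:
    """Per-joint time programs; joints absent from ``entries`` stay still."""

    entries: dict[int, JointRamp] = field(default_factory=dict)

    def scaled(self, factors: dict[int, float]) -> "JointProgram":
        out = {}
        for k, ramp in self.entries.items():
            f = factors.get(k, 1.0)
            out[k] = replace(ramp, amp_z=ramp.amp_z * f, amp_y=ramp.amp_y * f,
                             amp_x=ramp.amp_x * f)
        return JointProgram(out)


@dataclass
class NoiseModel:
    """Isotropic Gaussian marker noise plus independent per-frame dropout."""

    sigma_mm: float = 0.05
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_mm < 0:
            raise ParameterError("noise sigma must be >= 0")
        if not 0 <= self.dropout < 1:
            raise ParameterError("dropout probability must lie in [0, 1)")


# ---------------------------------------------------------------------------
# Chain model
# ---------------------------------------------------------------------------

@dataclass
class ChainModel:
    """Reference geometry of one simulated animal.

    ``bone_names[0]`` is the neurocranium, then vertebrae cranial to caudal;
    the last vertebra is the fixed base. ``ref_poses[k]`` is the
    world-from-bone reference transform, ``pivots[k]`` the world position of
    joint ``k`` (between bones ``k-1`` and ``k``) in the reference pose.
    Marker placements are bone-frame coordinates (mm).
    """

    species: str
    bone_names: list[str]
    ref_poses: np.ndarray
    pivots: dict[int, np.ndarray]
    markers: dict[str, dict[str, np.ndarray]]
    body_plane_markers: dict[str, np.ndarray]
    frame_rate: float
    filter_cutoff_hz: float
    elevation_threshold_deg: float = 5.0
    whole_body_motion: bool = False
    whole_body_velocity_mm_s: np.ndarray = field(
        default_factory=lambda: np.zeros(3))

    @property
    def n_bones(self) -> int:
        return len(self.bone_names)

    @property
    def n_vertebrae(self) -> int:
        return self.n_bones - 1

    @property
    def n_joints(self) -> int:
        return self.n_bones - 1

    def config(self) -> ChainConfig:
        """Chain configuration consumed by the analysis pipeline.

        Joint ACSs are placed at the joint pivots with world-aligned axes in
        the reference pose, so both ACSs of every joint coincide there and all
        DOF are zero at reference.
        """
        bones = []
        for i, name in enumerate(self.bone_names):
            W_inv = inv_rigid(self.ref_poses[i])
            acs = {}
            for k in (i, i + 1):  # joints bordering bone i
                if 1 <= k <= self.n_joints:
                    P = W_inv @ hom(t=self.pivots[k])
                    acs[k] = AnatomicalCoordinateSystem(name, P[:3, 3], P[:3, :3])
            if i == self.n_bones - 1:
                acs["caudal"] = AnatomicalCoordinateSystem(
                    name, np.zeros(3), inv_rigid(self.ref_poses[i])[:3, :3])
            bones.append(BoneSpec(name=name, markers=dict(self.markers[name]),
                                  centrum=np.zeros(3), acs=acs,
                                  ref_pose=self.ref_poses[i].copy()))
        base_inv = inv_rigid(self.ref_poses[-1])
        P = base_inv @ hom(t=self.pivots[1])
        body_plane = BodyPlaneSpec(
            markers=dict(self.body_plane_markers),
            acs=AnatomicalCoordinateSystem(BODY_PLANE, P[:3, 3], P[:3, :3]),
            ref_pose=self.ref_poses[-1].copy(),
        )
        return ChainConfig(species=self.species, frame_rate=self.frame_rate,
                           filter_cutoff_hz=self.filter_cutoff_hz,
                           bones=bones, body_plane=body_plane,
                           elevation_threshold_deg=self.elevation_threshold_deg)


def _vertebra_markers(length: float) -> list[np.ndarray]:
    """Four bone-fixed beads per vertebra: two in the centrum, one at the
    neural-spine tip, one on the ventral process.

    The dorsoventral spread (spine tip at 1.8 centrum lengths, ventral process
    at -0.8) keeps the analytic z-rotation noise floor of a single-frame pose
    fit, ``sigma / sqrt(sum(x^2 + y^2))``, at or below ~0.15 deg per bone for
    0.05 mm marker noise — the usual placement rule of maximising marker
    spread within the bone."""
    L = length
    return [np.array([0.45 * L, -0.50 * L, 0.12 * L]),
            np.array([-0.45 * L, -0.45 * L, -0.10 * L]),
            np.array([0.10 * L, 1.80 * L, 0.08 * L]),
            np.array([-0.20 * L, -0.80 * L, -0.12 * L])]


def _neurocranium_markers(length: float) -> list[np.ndarray]:
    L = length
    return [np.array([0.30 * L, 0.08 * L, 0.05 * L]),
            np.array([-0.25 * L, 0.12 * L, -0.07 * L]),
            np.array([0.10 * L, -0.10 * L, 0.13 * L]),
            np.array([-0.15 * L, -0.06 * L, -0.12 * L])]


def build_chain(species: str, centrum_lengths_mm: np.ndarray,
                neuro_length_mm: float, frame_rate: float,
                filter_cutoff_hz: float,
                initial_joint_offsets_deg: dict[int, float] | None = None,
                body_plane_layout: str = "midsagittal",
                whole_body_motion: bool = False,
                whole_body_velocity_mm_s=(0.0, 0.0, 0.0)) -> ChainModel:
    """Assemble a chain laid cranially along +x from a fixed caudal base.

    ``initial_joint_offsets_deg`` bakes a static sagittal curvature into the
    reference pose (positive = dorsal extension of the cranial bone).
    """
    lengths = np.asarray(centrum_lengths_mm, dtype=float)
    n = len(lengths)
    offsets = initial_joint_offsets_deg or {}
    names = [NEUROCRANIUM] + [f"v{k:02d}" for k in range(1, n + 1)]
    ref = np.zeros((n + 1, 4, 4))
    pivots: dict[int, np.ndarray] = {}
    R = np.eye(3)
    p = np.zeros(3)  # caudal end of the bone being placed
    for k in range(n, 0, -1):  # vertebrae, caudal to cranial
        L = lengths[k - 1]
        centroid = p + R @ np.array([L / 2.0, 0.0, 0.0])
        cranial_end = p + R @ np.array([L, 0.0, 0.0])
        ref[k] = hom(R, centroid)
        pivots[k] = cranial_end
        off = np.deg2rad(offsets.get(k, 0.0))
        R = R @ Rotation.from_euler("z", off).as_matrix()
        p = cranial_end
    centroid = p + R @ np.array([0.4 * neuro_length_mm, 0.0, 0.0])
    ref[0] = hom(R, centroid)

    markers: dict[str, dict[str, np.ndarray]] = {}
    markers[NEUROCRANIUM] = {f"{NEUROCRANIUM}_m{j + 1}": pos for j, pos
                             in enumerate(_neurocranium_markers(neuro_length_mm))}
    for k in range(1, n + 1):
        name = names[k]
        markers[name] = {f"{name}_m{j + 1}": pos for j, pos
                         in enumerate(_vertebra_markers(lengths[k - 1]))}
    if body_plane_layout == "midsagittal":  # trout: deep and superficial rows
        bp = [np.array([x, y, 0.0]) for x in (-30.0, -15.0, 0.0)
              for y in (6.0, 14.0)]
    elif body_plane_layout == "bilateral":  # frogfish: left and right rows
        bp = [np.array([x, 10.0, z]) for x in (-25.0, -10.0, 5.0)
              for z in (8.0, -8.0)]
    else:
        raise ParameterError(f"unknown body plane layout {body_plane_layout!r}")
    body_plane_markers = {f"{BODY_PLANE}_m{j + 1}": pos for j, pos in enumerate(bp)}
    return ChainModel(species=species, bone_names=names, ref_poses=ref,
                      pivots=pivots, markers=markers,
                      body_plane_markers=body_plane_markers,
                      frame_rate=frame_rate, filter_cutoff_hz=filter_cutoff_hz,
                      whole_body_motion=whole_body_motion,
                      whole_body_velocity_mm_s=np.asarray(
                          whole_body_velocity_mm_s, dtype=float))


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def build_preset(name: str, n_vertebrae: int | None = None,
                 frame_rate: float | None = None,
                 filter_cutoff_hz: float | None = None,
                 whole_body_motion: bool | None = None) -> ChainModel:
    """Trout-like or frogfish-like chain with study-condition defaults."""
    if name == "trout":
        n = 25 if n_vertebrae is None else n_vertebrae
        chain = build_chain(
            species="trout",
            centrum_lengths_mm=np.full(n, 5.0),
            neuro_length_mm=60.0,
            frame_rate=500.0 if frame_rate is None else frame_rate,
            filter_cutoff_hz=60.0 if filter_cutoff_hz is None else filter_cutoff_hz,
            body_plane_layout="midsagittal",
            whole_body_motion=True if whole_body_motion is None else whole_body_motion,
            whole_body_velocity_mm_s=(250.0, 40.0, 0.0),
        )
    elif name == "frogfish":
        n = 18 if n_vertebrae is None else n_vertebrae
        offsets = {2: -5.0, 3: -5.0, 4: -3.0, 5: -2.0,
                   9: 3.0, 10: 3.0, 11: 3.0, 12: 2.0, 13: 2.0}
        chain = build_chain(
            species="frogfish",
            centrum_lengths_mm=np.linspace(9.0, 4.0, n),
            neuro_length_mm=50.0,
            frame_rate=1000.0 if frame_rate is None else frame_rate,
            filter_cutoff_hz=100.0 if filter_cutoff_hz is None else filter_cutoff_hz,
            initial_joint_offsets_deg={k: v for k, v in offsets.items() if k <= n},
            body_plane_layout="bilateral",
            whole_body_motion=False if whole_body_motion is None else whole_body_motion,
        )
    else:
        raise ParameterError(f"unknown preset {name!r}")
    return chain


def preset_program(species: str) -> JointProgram:
    """Default joint program emulating each species' typical strike kinematics.

    Trout: small dorsal rotations (<= ~2 deg) over the first 12 joints summing
    to ~11 deg of elevation. Frogfish: 18 and 24 deg at the craniovertebral
    and first intervertebral joints, smaller dorsal rotations caudally and
    ventral rotation over joints 7-9, summing to ~45 deg.
    """
    if species == "trout":
        amps = [1.9, 1.6, 1.4, 1.2, 1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3]
        return JointProgram({k: JointRamp(a, onset_s=0.02, rise_s=0.08)
                             for k, a in enumerate(amps, start=1)})
    if species == "frogfish":
        amps = {1: 18.0, 2: 24.0, 3: 5.0, 4: 3.0, 5: 2.0, 6: 1.0,
                7: -3.0, 8: -3.0, 9: -3.0, 10: 1.0, 11: -1.0, 12: 1.0}
        return JointProgram({k: JointRamp(a, onset_s=0.01, rise_s=0.03)
                             for k, a in amps.items()})
    raise ParameterError(f"unknown species {species!r}")


def preset_duration_s(species: str) -> float:
    """Default recording window: brackets the programmed strike (onset to
    peak) with a trailing margin so neither the baseline frame nor the peak
    frame sits on a filter edge."""
    return {"trout": 0.14, "frogfish": 0.065}[species]


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _forward_kinematics(chain: ChainModel, angles: dict[int, np.ndarray]
                        ) -> np.ndarray:
    """World poses (n_bones, n_frames, 4, 4) from per-joint angle traces.

    Joint angles are in the measurement convention: the relative rotation of
    the caudal ACS in the cranial ACS frame is ``Rz(-z) Ry(y) Rx(x)``
    (intrinsic), so positive z rotates the cranial bone dorsally.
    """
    some = next(iter(angles.values()))
    n_frames = len(some)
    W = np.zeros((chain.n_bones, n_frames, 4, 4))
    W[-1] = chain.ref_poses[-1]
    for k in range(chain.n_joints, 0, -1):  # joint k moves bone k-1
        ang = angles[k]
        # inverse of the distal-in-proximal relative rotation
        zyx = np.column_stack([-ang[:, 0], ang[:, 1], ang[:, 2]])
        R_hat = Rotation.from_euler("ZYX", zyx, degrees=True).inv().as_matrix()
        pivot = chain.pivots[k]
        A = np.zeros((n_frames, 4, 4))
        A[:, :3, :3] = R_hat
        A[:, :3, 3] = pivot - R_hat @ pivot
        A[:, 3, 3] = 1.0
        link = inv_rigid(chain.ref_poses[k]) [None] @ A @ chain.ref_poses[k - 1][None]
        W[k - 1] = W[k] @ link
    return W


def simulate_strike(chain: ChainModel, program: JointProgram,
                    duration_s: float | None = None,
                    noise: NoiseModel | None = None,
                    strike_id: str = "strike", individual_id: str = "sim"
                    ) -> StrikeRecording:
    """Simulate one strike: markers (optionally noisy), ground-truth poses and
    the realised joint-angle traces."""
    if duration_s is None:
        duration_s = preset_duration_s(chain.species)
    for k, ramp in program.entries.items():
        if not 1 <= k <= chain.n_joints:
            raise ParameterError(f"program references absent joint {k}")
        if ramp.onset_s + ramp.rise_s > duration_s + 1e-12:
            raise ParameterError(
                f"joint {k}: ramp (onset {ramp.onset_s}s + rise {ramp.rise_s}s)"
                f" exceeds recording duration {duration_s}s"
            )
    n_frames = int(round(duration_s * chain.frame_rate)) + 1
    t = np.arange(n_frames) / chain.frame_rate
    angles = {k: (program.entries[k].angles(t) if k in program.entries
                  else np.zeros((n_frames, 3)))
              for k in range(1, chain.n_joints + 1)}
    W = _forward_kinematics(chain, angles)
    if chain.whole_body_motion:
        G = np.tile(np.eye(4), (n_frames, 1, 1))
        G[:, :3, 3] = np.outer(t, chain.whole_body_velocity_mm_s)
        W = G[None] @ W

    marker_names: list[str] = []
    columns: list[np.ndarray] = []
    for i, bone in enumerate(chain.bone_names):
        for mname, p in chain.markers[bone].items():
            marker_names.append(mname)
            columns.append(W[i, :, :3, :3] @ p + W[i, :, :3, 3])
    for mname, p in chain.body_plane_markers.items():
        marker_names.append(mname)
        columns.append(W[-1, :, :3, :3] @ p + W[-1, :, :3, 3])
    positions = np.stack(columns, axis=1)

    if noise is not None and (noise.sigma_mm > 0 or noise.dropout > 0):
        rng = np.random.default_rng(noise.seed)
        if noise.sigma_mm > 0:
            positions = positions + rng.normal(0.0, noise.sigma_mm,
                                               positions.shape)
        if noise.dropout > 0:
            drop = rng.random(positions.shape[:2]) < noise.dropout
            positions[drop] = np.nan

    mset = MarkerTrajectorySet(frame_rate=chain.frame_rate,
                               markers=marker_names, positions=positions)
    poses = {bone: PoseMatrixSequence(bone_name=bone, transforms=W[i].copy())
             for i, bone in enumerate(chain.bone_names)}
    poses[BODY_PLANE] = PoseMatrixSequence(bone_name=BODY_PLANE,
                                           transforms=W[-1].copy())
    ground_truth = {
        "joint_angles_deg": {k: v.copy() for k, v in angles.items()},
        "program": program,
        "elevation_deg": sum(v[:, 0] for v in angles.values()),
    }
    return StrikeRecording(strike_id=strike_id, individual_id=individual_id,
                           species=chain.species, frame_rate=chain.frame_rate,
                           config=chain.config(), markers=mset, poses=poses,
                           ground_truth=ground_truth)


def strike_seed(seed: int, index: int) -> int:
    """Deterministic per-strike noise seed, kept below 2**31."""
    return (seed * 1000003 + 7919 * index) % (2 ** 31)


def strike_cohort(chain: ChainModel, program: JointProgram, n: int, seed: int,
                  amplitude_jitter_frac: float = 0.15,
                  noise: NoiseModel | None = None,
                  duration_s: float | None = None,
                  individual_id: str = "sim") -> list[StrikeRecording]:
    """Reproducible cohort of strikes with per-strike amplitude jitter.

    Strike vigor varies as a whole: one Gaussian factor
    ``1 + N(0, amplitude_jitter_frac)`` per strike scales every programmed
    amplitude, so joint rotations covary across strikes the way repeated
    feeding events do. Marker noise uses a seed derived from ``seed`` and the
    strike index via :func:`strike_seed`.
    """
    if n < 1:
        raise ParameterError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        f = 1.0 + rng.normal(0.0, amplitude_jitter_frac)
        factors = {k: f for k in program.entries}
        strike_noise = (None if noise is None
                        else replace(noise, seed=strike_seed(seed, i)))
        out.append(simulate_strike(
            chain, program.scaled(factors), duration_s=duration_s,
            noise=strike_noise, strike_id=f"{individual_id}_s{i:03d}",
            individual_id=individual_id))
    return out
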