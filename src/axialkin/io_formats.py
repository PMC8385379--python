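"""Tabular I/O and chain configuration.

Three on-disk artefacts are supported, all plain text:

* **Marker trajectory CSV** (``wide-xyz`` dialect): one row per frame, columns
  ``<marker>_X, <marker>_Y, <marker>_Z`` in millimetres, comma separated, with a
  mandatory header row. Missing observations are empty cells. Leading comment
  lines start with ``#``; ``# frame_rate_hz=<r>`` carries the capture rate so a
  written file round-trips the rate exactly.
* **Pose matrix CSV**: one row per frame, 16 row-major values of the 4x4
  *world-from-bone* homogeneous transform. An all-empty row is a tracking gap.
* **Chain configuration** (YAML): ordered bone list (neurocranium first, then
  vertebra 1..N), per-bone marker placements and anatomical coordinate systems
  (both in the bone's reference frame), the body-plane pseudo-bone, frame rate,
  Butterworth cut-off and the cranial-elevation inclusion threshold.

Frames are 0-based; time of frame ``i`` is ``i / frame_rate`` seconds. Units
are fixed at millimetres and degrees throughout the package.
"""
from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import _rigid
from .coordinate_systems import AnatomicalCoordinateSystem
from .errors import ConfigError, FormatError, ParameterError, ValidationError

_FLOAT_FMT = "%.17g"

#: Default Butterworth cut-offs (Hz) per species preset.
SPECIES_FILTER_DEFAULTS = {"trout": 60.0, "frogfish": 100.0}
SPECIES_FRAME_RATES = {"trout": 500.0, "frogfish": 1000.0}


# ---------------------------------------------------------------------------
# Marker trajectories
# ---------------------------------------------------------------------------

@dataclass
class MarkerTrajectorySet:
    """Time series of named 3-D marker positions (mm, world frame).

    ``positions`` has shape ``(n_frames, n_markers, 3)``; a missing observation
    is NaN in all three components of its frame/marker slot.
    """

    frame_rate: float
    markers: list[str]
    positions: np.ndarray

    def __post_init__(self) -> None:
        if not self.frame_rate > 0:
            raise ParameterError(f"frame_rate must be > 0, got {self.frame_rate}")
        if len(set(self.markers)) != len(self.markers):
            raise ValidationError("marker names must be unique")
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[1:] != (len(self.markers), 3):
            raise ValidationError(
                f"positions shape {self.positions.shape} inconsistent with "
                f"{len(self.markers)} markers"
            )
        if np.isinf(self.positions).any():
            raise ValidationError("marker positions must be finite or NaN (missing)")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def index(self, marker: str) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise KeyError(f"unknown marker {marker!r}") from None

    def get(self, marker: str) -> np.ndarray:
        """Trajectory of one marker, shape (n_frames, 3)."""
        return self.positions[:, self.index(marker), :]

    def present(self) -> np.ndarray:
        """Boolean (n_frames, n_markers) mask of non-missing observations."""
        return ~np.isnan(self.positions).any(axis=2)


def _read_comment_header(path) -> tuple[dict[str, str], list[str]]:
    meta: dict[str, str] = {}
    lines: list[str] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, val = body.split("=", 1)
                    meta[key.strip()] = val.strip()
            else:
                lines.append(line)
    return meta, lines


def read_marker_csv(path, dialect: str = "wide-xyz",
                    frame_rate: float | None = None) -> MarkerTrajectorySet:
    """Read a marker trajectory CSV (``wide-xyz`` dialect).

    ``frame_rate`` overrides the ``# frame_rate_hz`` comment; one of the two
    must be available.
    """
    if dialect != "wide-xyz":
        raise ParameterError(f"unsupported dialect {dialect!r}")
    meta, lines = _read_comment_header(path)
    if frame_rate is None:
        if "frame_rate_hz" not in meta:
            raise FormatError(f"{path}: no frame_rate_hz header and none supplied")
        frame_rate = float(meta["frame_rate_hz"])
    rows = list(csv.reader(io.StringIO("".join(lines))))
    rows = [r for r in rows if r]  # drop blank lines
    if not rows:
        raise FormatError(f"{path}: empty file (no header row)")
    header = [h.strip() for h in rows[0]]
    if header and header[0].lower() == "frame":
        drop_first = True
        header = header[1:]
    else:
        drop_first = False
    if len(header) % 3 != 0:
        raise FormatError(f"{path}: column count {len(header)} is not a multiple of 3")
    markers: list[str] = []
    for i in range(0, len(header), 3):
        triplet = header[i:i + 3]
        suffixes = [c.rsplit("_", 1)[-1].upper() for c in triplet]
        names = {c.rsplit("_", 1)[0] for c in triplet}
        if suffixes != ["X", "Y", "Z"] or len(names) != 1:
            raise FormatError(
                f"{path}: expected <marker>_X,_Y,_Z triplet, got column {triplet[0]!r}"
            )
        markers.append(names.pop())
    ncol = len(header) + (1 if drop_first else 0)
    data = np.full((len(rows) - 1, len(markers) * 3), np.nan)
    for rno, row in enumerate(rows[1:], start=2):
        if len(row) != ncol:
            raise FormatError(
                f"{path}: row {rno} has {len(row)} fields, expected {ncol}"
            )
        vals = row[1:] if drop_first else row
        for cno, cell in enumerate(vals):
            cell = cell.strip()
            if cell in ("", "nan", "NaN"):
                continue
            try:
                data[rno - 2, cno] = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: row {rno}, column {header[cno]!r}: "
                    f"not a number: {cell!r}"
                ) from None
    positions = data.reshape(len(rows) - 1, len(markers), 3)
    # a marker with any missing component that frame is missing entirely
    positions[np.isnan(positions).any(axis=2)] = np.nan
    return MarkerTrajectorySet(frame_rate=frame_rate, markers=markers,
                               positions=positions)


def write_marker_csv(mset: MarkerTrajectorySet, path) -> None:
    """Write a marker trajectory CSV re-readable by :func:`read_marker_csv`."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# frame_rate_hz={_FLOAT_FMT % mset.frame_rate}\n")
        writer = csv.writer(fh)
        header = []
        for m in mset.markers:
            header += [f"{m}_X", f"{m}_Y", f"{m}_Z"]
        writer.writerow(header)
        flat = mset.positions.reshape(mset.n_frames, 3 * len(mset.markers))
        for row in flat:
            writer.writerow(["" if np.isnan(v) else _FLOAT_FMT % v for v in row])


# ---------------------------------------------------------------------------
# Pose matrix sequences
# ---------------------------------------------------------------------------

@dataclass
class PoseMatrixSequence:
    """Per-frame 4x4 rigid transforms (world-from-bone, mm).

    A gap (untracked frame) is an all-NaN 4x4. Non-gap frames satisfy
    R^T R = I and det R = +1 to within ``atol``.
    """

    bone_name: str
    transforms: np.ndarray
    atol: float = _rigid.RIGID_ATOL

    def __post_init__(self) -> None:
        self.transforms = np.asarray(self.transforms, dtype=float)
        if self.transforms.ndim != 3 or self.transforms.shape[1:] != (4, 4):
            raise ValidationError("transforms must have shape (n_frames, 4, 4)")
        for i in np.nonzero(~self.is_gap)[0]:
            err = _rigid.rigidity_error(self.transforms[i])
            if err > self.atol:
                raise ValidationError(
                    f"{self.bone_name}: frame {i} is not a rigid transform "
                    f"(error {err:.3g} > {self.atol:.3g})"
                )

    @property
    def n_frames(self) -> int:
        return self.transforms.shape[0]

    @property
    def is_gap(self) -> np.ndarray:
        return np.isnan(self.transforms).any(axis=(1, 2))

    def segments(self) -> list[tuple[int, int]]:
        """Half-open [start, stop) runs of consecutive non-gap frames."""
        ok = ~self.is_gap
        out: list[tuple[int, int]] = []
        start = None
        for i, flag in enumerate(ok):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                out.append((start, i))
                start = None
        if start is not None:
            out.append((start, len(ok)))
        return out


_POSE_COLS = [f"a{r}{c}" for r in range(4) for c in range(4)]


def read_pose_csv(path, bone_name: str | None = None) -> PoseMatrixSequence:
    """Read a 16-column row-major pose CSV; enforce orthonormality within 1e-6."""
    meta, lines = _read_comment_header(path)
    if bone_name is None:
        bone_name = meta.get("bone", "bone")
    rows = [r for r in csv.reader(io.StringIO("".join(lines))) if r]
    if not rows:
        raise FormatError(f"{path}: empty pose file")
    start = 1 if not _is_numeric_row(rows[0]) else 0
    data_rows = rows[start:]
    T = np.full((len(data_rows), 4, 4), np.nan)
    for i, row in enumerate(data_rows):
        if len(row) != 16:
            raise FormatError(f"{path}: row {i + start + 1} has {len(row)} fields, expected 16")
        cells = [c.strip() for c in row]
        if all(c in ("", "nan", "NaN") for c in cells):
            continue  # gap frame
        try:
            vals = np.array([float(c) for c in cells]).reshape(4, 4)
        except ValueError:
            raise FormatError(f"{path}: row {i + start + 1}: non-numeric cell") from None
        R = vals[:3, :3]
        err = max(float(np.max(np.abs(R.T @ R - np.eye(3)))),
                  abs(float(np.linalg.det(R)) - 1.0),
                  float(np.max(np.abs(vals[3] - [0, 0, 0, 1]))))
        if err > 1e-6:
            raise ValidationError(
                f"{path}: frame {i} is not a proper rigid transform (error {err:.3g})"
            )
        vals[:3, :3] = _rigid.nearest_rotation(R)
        vals[3] = [0.0, 0.0, 0.0, 1.0]
        T[i] = vals
    return PoseMatrixSequence(bone_name=bone_name, transforms=T)


def _is_numeric_row(row: list[str]) -> bool:
    for cell in row:
        cell = cell.strip()
        if cell in ("", "nan", "NaN"):
            continue
        try:
            float(cell)
        except ValueError:
            return False
    return True


def write_pose_csv(seq: PoseMatrixSequence, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# bone={seq.bone_name}\n")
        fh.write("# convention=world_from_bone,row_major,mm\n")
        writer = csv.writer(fh)
        writer.writerow(_POSE_COLS)
        for i in range(seq.n_frames):
            flat = seq.transforms[i].reshape(16)
            writer.writerow(["" if np.isnan(v) else _FLOAT_FMT % v for v in flat])


# ---------------------------------------------------------------------------
# Chain configuration
# ---------------------------------------------------------------------------

@dataclass
class BoneSpec:
    """One bone of the chain: markers, landmarks and ACS placements, all in the
    bone's own reference frame (mm)."""

    name: str
    markers: dict[str, np.ndarray] = field(default_factory=dict)
    rotoscoped: bool = False
    centrum: np.ndarray | None = None
    acs: dict[object, AnatomicalCoordinateSystem] = field(default_factory=dict)
    ref_pose: np.ndarray | None = None


@dataclass
class BodyPlaneSpec:
    """The intramuscular-marker body plane, treated as a rigid pseudo-bone."""

    markers: dict[str, np.ndarray] = field(default_factory=dict)
    acs: AnatomicalCoordinateSystem | None = None
    ref_pose: np.ndarray | None = None


@dataclass
class ChainConfig:
    """Topology and settings of one animal's cranio-vertebral chain.

    ``bones[0]`` is the neurocranium, ``bones[k]`` is vertebra ``k``. Joint
    ``k`` (1-based; joint 1 = craniovertebral) connects ``bones[k-1]``
    (cranial) and ``bones[k]`` (caudal).
    """

    species: str
    frame_rate: float
    filter_cutoff_hz: float
    bones: list[BoneSpec]
    body_plane: BodyPlaneSpec | None = None
    elevation_threshold_deg: float = 5.0
    filter_order: int = 2

    def __post_init__(self) -> None:
        if not self.frame_rate > 0:
            raise ConfigError("frame_rate must be positive")
        if not 0 < self.filter_cutoff_hz < self.frame_rate / 2:
            raise ConfigError(
                f"filter cutoff {self.filter_cutoff_hz} Hz must lie below the "
                f"Nyquist rate {self.frame_rate / 2} Hz"
            )
        names = [b.name for b in self.bones]
        if len(set(names)) != len(names):
            raise ConfigError("bone names must be unique")
        if len(self.bones) < 2:
            raise ConfigError("a chain needs at least two bones")

    @property
    def bone_names(self) -> list[str]:
        return [b.name for b in self.bones]

    @property
    def n_joints(self) -> int:
        return len(self.bones) - 1

    @property
    def n_vertebrae(self) -> int:
        return len(self.bones) - 1

    def bone(self, name: str) -> BoneSpec:
        for b in self.bones:
            if b.name == name:
                return b
        raise ConfigError(f"unknown bone {name!r}")

    def joints(self) -> list[tuple[int, str, str]]:
        """(joint index, cranial bone, caudal bone) for joints 1..N."""
        return [(k, self.bones[k - 1].name, self.bones[k].name)
                for k in range(1, len(self.bones))]

    def caudal_acs(self) -> AnatomicalCoordinateSystem:
        """ACS on the caudal-most vertebra used as the curvature reference."""
        base = self.bones[-1]
        if "caudal" in base.acs:
            return base.acs["caudal"]
        origin = base.centrum if base.centrum is not None else np.zeros(3)
        return AnatomicalCoordinateSystem(base.name, np.asarray(origin, float),
                                          np.eye(3))


def _acs_from_dict(bone: str, d: dict) -> AnatomicalCoordinateSystem:
    axes = np.array(d["axes"], dtype=float)
    return AnatomicalCoordinateSystem(bone, np.array(d["origin"], dtype=float),
                                      axes.T)  # stored as rows x,y,z -> columns


def _acs_to_dict(acs: AnatomicalCoordinateSystem) -> dict:
    return {"origin": [float(v) for v in acs.origin],
            "axes": [[float(v) for v in acs.orientation[:, i]] for i in range(3)]}


def load_chain_config(path) -> ChainConfig:
    """Load and validate a chain configuration YAML file.

    A file containing only ``preset: trout|frogfish`` (plus optional overrides
    such as ``n_vertebrae``) expands to the corresponding synthetic preset's
    configuration.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    if "preset" in raw:
        from .synthetic_chain import build_preset  # lazy: avoid import cycle

        name = raw.pop("preset")
        return build_preset(name, **raw).config()
    return chain_config_from_dict(raw)


def chain_config_from_dict(raw: dict) -> ChainConfig:
    species = raw.get("species", "custom")
    frame_rate = float(raw.get("frame_rate", SPECIES_FRAME_RATES.get(species, 0)))
    cutoff = raw.get("filter_cutoff_hz", SPECIES_FILTER_DEFAULTS.get(species))
    if cutoff is None:
        raise ConfigError("filter_cutoff_hz missing and no species default")
    bones = []
    for b in raw.get("bones", []):
        markers = {k: np.array(v, dtype=float) for k, v in (b.get("markers") or {}).items()}
        acs = {}
        for key, val in (b.get("acs") or {}).items():
            acs_key: object = key if key == "caudal" else int(key)
            acs[acs_key] = _acs_from_dict(b["name"], val)
        bones.append(BoneSpec(
            name=b["name"], markers=markers,
            rotoscoped=bool(b.get("rotoscoped", False)),
            centrum=None if b.get("centrum") is None else np.array(b["centrum"], float),
            acs=acs,
            ref_pose=None if b.get("ref_pose") is None else np.array(b["ref_pose"], float),
        ))
    bone_names = {b.name for b in bones}
    for j in raw.get("joints", []):
        for side in ("cranial", "caudal"):
            if j.get(side) is not None and j[side] not in bone_names:
                raise ConfigError(f"joint {j.get('index')} references unknown bone {j[side]!r}")
    body_plane = None
    if raw.get("body_plane"):
        bp = raw["body_plane"]
        body_plane = BodyPlaneSpec(
            markers={k: np.array(v, dtype=float) for k, v in (bp.get("markers") or {}).items()},
            acs=_acs_from_dict("body_plane", bp["acs"]) if bp.get("acs") else None,
            ref_pose=None if bp.get("ref_pose") is None else np.array(bp["ref_pose"], float),
        )
    return ChainConfig(
        species=species, frame_rate=frame_rate, filter_cutoff_hz=float(cutoff),
        bones=bones, body_plane=body_plane,
        elevation_threshold_deg=float(raw.get("elevation_threshold_deg", 5.0)),
        filter_order=int(raw.get("filter_order", 2)),
    )


def chain_config_to_dict(cfg: ChainConfig) -> dict:
    out: dict = {
        "species": cfg.species,
        "frame_rate": float(cfg.frame_rate),
        "filter_cutoff_hz": float(cfg.filter_cutoff_hz),
        "elevation_threshold_deg": float(cfg.elevation_threshold_deg),
        "filter_order": int(cfg.filter_order),
        "bones": [],
    }
    for b in cfg.bones:
        entry: dict = {"name": b.name, "rotoscoped": bool(b.rotoscoped)}
        if b.markers:
            entry["markers"] = {k: [float(x) for x in v] for k, v in b.markers.items()}
        if b.centrum is not None:
            entry["centrum"] = [float(x) for x in b.centrum]
        if b.acs:
            entry["acs"] = {str(k): _acs_to_dict(v) for k, v in b.acs.items()}
        if b.ref_pose is not None:
            entry["ref_pose"] = [[float(x) for x in row] for row in b.ref_pose]
        out["bones"].append(entry)
    if cfg.body_plane is not None:
        bp: dict = {}
        if cfg.body_plane.markers:
            bp["markers"] = {k: [float(x) for x in v]
                             for k, v in cfg.body_plane.markers.items()}
        if cfg.body_plane.acs is not None:
            bp["acs"] = _acs_to_dict(cfg.body_plane.acs)
        if cfg.body_plane.ref_pose is not None:
            bp["ref_pose"] = [[float(x) for x in row] for row in cfg.body_plane.ref_pose]
        out["body_plane"] = bp
    out["joints"] = [{"index": k, "cranial": a, "caudal": b}
                     for k, a, b in cfg.joints()]
    return out


def save_chain_config(cfg: ChainConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(chain_config_to_dict(cfg), fh, sort_keys=False)
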