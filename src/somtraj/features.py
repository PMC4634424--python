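"""Skeleton frames, body-plane coordinates and per-frame kinematic features.

A motion trajectory is an ordered list of :class:`SkeletonFrame` objects, each
holding the 20 named joints of a first-generation depth-sensor skeleton in
world coordinates (meters).  Frames are re-expressed in a subject-centred
"body-plane" coordinate system anchored at the spine, and then summarised by a
71-dimensional feature vector: the 19 unit direction vectors of the skeleton's
kinematic-tree edges (3 x 19 components) plus 14 joint angles (radians),
3 x 19 + 14 = 71.

The body-plane axes are chosen so that the X-Y plane is the coronal plane,
Y-Z the sagittal plane and X-Z the transverse plane, which makes the features
invariant to the subject's position, facing orientation and overall height.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "JOINT_NAMES",
    "SEGMENTS",
    "ANGLE_SITES",
    "FEATURE_DIM",
    "SkeletonFrame",
    "BodyFrameBasis",
    "FeatureVector",
    "DegenerateFrameError",
    "compute_body_basis",
    "to_body_coordinates",
    "extract_features",
    "features_to_array",
    "trajectory_to_array",
    "read_frames_csv",
    "write_frames_csv",
    "read_frames_jsonl",
    "write_frames_jsonl",
]

#: The 20 joints of the first-generation depth-sensor skeleton, fixed order.
JOINT_NAMES: tuple[str, ...] = (
    "hip_center",
    "spine",
    "shoulder_center",
    "head",
    "shoulder_left",
    "elbow_left",
    "wrist_left",
    "hand_left",
    "shoulder_right",
    "elbow_right",
    "wrist_right",
    "hand_right",
    "hip_left",
    "knee_left",
    "ankle_left",
    "foot_left",
    "hip_right",
    "knee_right",
    "ankle_right",
    "foot_right",
)

#: The 19 edges of the 20-joint kinematic tree, ordered (parent, child).
#: A tree on 20 nodes has exactly 19 edges; their unit direction vectors are
#: the first 57 feature components, in this order.
SEGMENTS: tuple[tuple[str, str], ...] = (
    ("hip_center", "spine"),
    ("spine", "shoulder_center"),
    ("shoulder_center", "head"),
    ("shoulder_center", "shoulder_left"),
    ("shoulder_left", "elbow_left"),
    ("elbow_left", "wrist_left"),
    ("wrist_left", "hand_left"),
    ("shoulder_center", "shoulder_right"),
    ("shoulder_right", "elbow_right"),
    ("elbow_right", "wrist_right"),
    ("wrist_right", "hand_right"),
    ("hip_center", "hip_left"),
    ("hip_left", "knee_left"),
    ("knee_left", "ankle_left"),
    ("ankle_left", "foot_left"),
    ("hip_center", "hip_right"),
    ("hip_right", "knee_right"),
    ("knee_right", "ankle_right"),
    ("ankle_right", "foot_right"),
)

_SEGMENT_INDEX = {seg: i for i, seg in enumerate(SEGMENTS)}


def _site(name: str, proximal: tuple[str, str], distal: tuple[str, str]):
    return (name, _SEGMENT_INDEX[proximal], _SEGMENT_INDEX[distal])


#: The 14 angle sites: (site name, proximal segment idx, distal segment idx).
#: The angle is between the two connected segments' direction vectors, both
#: oriented parent->child, so a fully extended limb reads 0.
ANGLE_SITES: tuple[tuple[str, int, int], ...] = (
    _site("elbow_left", ("shoulder_left", "elbow_left"), ("elbow_left", "wrist_left")),
    _site("elbow_right", ("shoulder_right", "elbow_right"), ("elbow_right", "wrist_right")),
    _site("wrist_left", ("elbow_left", "wrist_left"), ("wrist_left", "hand_left")),
    _site("wrist_right", ("elbow_right", "wrist_right"), ("wrist_right", "hand_right")),
    _site("shoulder_left", ("shoulder_center", "shoulder_left"), ("shoulder_left", "elbow_left")),
    _site("shoulder_right", ("shoulder_center", "shoulder_right"), ("shoulder_right", "elbow_right")),
    _site("knee_left", ("hip_left", "knee_left"), ("knee_left", "ankle_left")),
    _site("knee_right", ("hip_right", "knee_right"), ("knee_right", "ankle_right")),
    _site("ankle_left", ("knee_left", "ankle_left"), ("ankle_left", "foot_left")),
    _site("ankle_right", ("knee_right", "ankle_right"), ("ankle_right", "foot_right")),
    _site("hip_left", ("hip_center", "hip_left"), ("hip_left", "knee_left")),
    _site("hip_right", ("hip_center", "hip_right"), ("hip_right", "knee_right")),
    _site("neck", ("spine", "shoulder_center"), ("shoulder_center", "head")),
    _site("trunk", ("hip_center", "spine"), ("spine", "shoulder_center")),
)

FEATURE_DIM = 3 * len(SEGMENTS) + len(ANGLE_SITES)
assert FEATURE_DIM == 71


class DegenerateFrameError(ValueError):
    """Raised when a frame cannot support the body-plane construction."""


@dataclass
class SkeletonFrame:
    """One time step of a skeletal recording: 20 named joints in meters."""

    joints: dict[str, np.ndarray]
    timestamp: float | None = None

    def __post_init__(self) -> None:
        self.joints = {k: np.asarray(v, dtype=float) for k, v in self.joints.items()}
        missing = set(JOINT_NAMES) - set(self.joints)
        if missing:
            raise ValueError(f"missing joints: {sorted(missing)}")
        for name in JOINT_NAMES:
            p = self.joints[name]
            if p.shape != (3,):
                raise ValueError(f"joint {name!r} is not a 3-vector")
            if not np.all(np.isfinite(p)):
                raise ValueError(f"joint {name!r} has non-finite coordinates")

    def as_array(self) -> np.ndarray:
        """Joint positions as a (20, 3) array in canonical joint order."""
        return np.stack([self.joints[name] for name in JOINT_NAMES])

    @classmethod
    def from_array(cls, arr: np.ndarray, timestamp: float | None = None) -> "SkeletonFrame":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(JOINT_NAMES), 3):
            raise ValueError(f"expected shape (20, 3), got {arr.shape}")
        return cls({name: arr[i] for i, name in enumerate(JOINT_NAMES)}, timestamp)


@dataclass
class BodyFrameBasis:
    """Orthonormal subject-centred basis at the spine.

    ``u`` points along the trunk (spine -> shoulder_center), ``v`` is the
    lateral direction obtained by orthogonalizing spine -> shoulder_left
    against ``u``, and ``w = u x v`` completes the right-handed triple.
    """

    origin: np.ndarray
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray


@dataclass
class FeatureVector:
    """Per-frame descriptor: 19 unit segment vectors and 14 joint angles."""

    segment_vectors: np.ndarray  # (19, 3), unit rows
    joint_angles: np.ndarray  # (14,), radians in [0, pi]

    def __post_init__(self) -> None:
        self.segment_vectors = np.asarray(self.segment_vectors, dtype=float)
        self.joint_angles = np.asarray(self.joint_angles, dtype=float)
        if self.segment_vectors.shape != (len(SEGMENTS), 3):
            raise ValueError("segment_vectors must have shape (19, 3)")
        if self.joint_angles.shape != (len(ANGLE_SITES),):
            raise ValueError("joint_angles must have shape (14,)")

    def __len__(self) -> int:
        return FEATURE_DIM

    def to_array(self, scale_angles: bool = True) -> np.ndarray:
        """Flatten to a length-71 vector.

        With ``scale_angles`` the angles are divided by pi so every component
        lies in [-1, 1]; this is the scaling used for map training, where
        raw radian angles would otherwise dominate the Euclidean metric.
        """
        angles = self.joint_angles / np.pi if scale_angles else self.joint_angles
        return np.concatenate([self.segment_vectors.ravel(), angles])


def compute_body_basis(frame: SkeletonFrame) -> BodyFrameBasis:
    """Build the subject-centred orthonormal basis anchored at the spine.

    Raises :class:`DegenerateFrameError` when spine, shoulder_center and
    shoulder_left are coincident or collinear.
    """
    origin = frame.joints["spine"]
    a = frame.joints["shoulder_center"] - origin
    b = frame.joints["shoulder_left"] - origin
    na = np.linalg.norm(a)
    if na < 1e-12:
        raise DegenerateFrameError("spine and shoulder_center coincide")
    u = a / na
    r = b - (b @ u) * u  # Gram-Schmidt residual against the trunk axis
    nr = np.linalg.norm(r)
    if nr < 1e-12:
        raise DegenerateFrameError(
            "spine, shoulder_center and shoulder_left are collinear"
        )
    v = r / nr
    w = np.cross(u, v)
    return BodyFrameBasis(origin=origin, u=u, v=v, w=w)


def to_body_coordinates(frame: SkeletonFrame, basis: BodyFrameBasis) -> SkeletonFrame:
    """Re-express all joints in the body-plane frame.

    A joint p maps to ((p-o).v, (p-o).u, (p-o).w): lateral, longitudinal and
    anterior components, so X-Y is the coronal plane.  The spine maps to the
    origin.
    """
    rot = np.stack([basis.v, basis.u, basis.w])  # rows: new x, y, z axes
    arr = (frame.as_array() - basis.origin) @ rot.T
    return SkeletonFrame.from_array(arr, frame.timestamp)


def extract_features(frame: SkeletonFrame) -> FeatureVector:
    """Compute the 71-D descriptor of a frame.

    The frame is first moved to body-plane coordinates; each of the 19 tree
    edges contributes its unit direction vector, and each of the 14 angle
    sites the angle (arccos of the dot product) between its two adjacent
    segment directions.
    """
    basis = compute_body_basis(frame)
    body = to_body_coordinates(frame, basis)
    arr = body.as_array()
    index = {name: i for i, name in enumerate(JOINT_NAMES)}

    directions = np.empty((len(SEGMENTS), 3))
    for i, (parent, child) in enumerate(SEGMENTS):
        d = arr[index[child]] - arr[index[parent]]
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise DegenerateFrameError(f"zero-length segment {parent}->{child}")
        directions[i] = d / n

    angles = np.empty(len(ANGLE_SITES))
    for i, (_, prox, dist) in enumerate(ANGLE_SITES):
        c = float(np.clip(directions[prox] @ directions[dist], -1.0, 1.0))
        angles[i] = np.arccos(c)

    return FeatureVector(segment_vectors=directions, joint_angles=angles)


def features_to_array(frame: SkeletonFrame) -> np.ndarray:
    """Scaled 71-vector of a frame (convenience for map training)."""
    return extract_features(frame).to_array(scale_angles=True)


def trajectory_to_array(frames: list[SkeletonFrame]) -> np.ndarray:
    """Stack scaled feature vectors of a trajectory into an (n, 71) array."""
    if not frames:
        raise ValueError("empty trajectory")
    return np.stack([features_to_array(f) for f in frames])


# ---------------------------------------------------------------------------
# Frame I/O: CSV (one row per frame, <joint>_{x,y,z} columns) and JSON-Lines.
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [f"{j}_{axis}" for j in JOINT_NAMES for axis in "xyz"]


def write_frames_csv(frames: list[SkeletonFrame], path) -> None:
    rows = [f.as_array().ravel() for f in frames]
    df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    if any(f.timestamp is not None for f in frames):
        df.insert(0, "timestamp", [f.timestamp for f in frames])
    df.to_csv(path, index=False)


def read_frames_csv(path) -> list[SkeletonFrame]:
    df = pd.read_csv(path)
    timestamps = df["timestamp"].to_numpy() if "timestamp" in df.columns else None
    arr = df[_CSV_COLUMNS].to_numpy(dtype=float).reshape(-1, len(JOINT_NAMES), 3)
    return [
        SkeletonFrame.from_array(a, float(timestamps[i]) if timestamps is not None else None)
        for i, a in enumerate(arr)
    ]


def write_frames_jsonl(frames: list[SkeletonFrame], path) -> None:
    with open(path, "w") as fh:
        for f in frames:
            obj = {"joints": {k: list(map(float, v)) for k, v in f.joints.items()}}
            if f.timestamp is not None:
                obj["timestamp"] = f.timestamp
            fh.write(json.dumps(obj) + "\n")


def read_frames_jsonl(path) -> list[SkeletonFrame]:
    frames = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            frames.append(SkeletonFrame(obj["joints"], obj.get("timestamp")))
    return frames
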