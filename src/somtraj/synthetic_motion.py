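"""Synthetic multi-subject skeletal recordings of coarse full-body exercises.

There is no public corpus of the depth-sensor recordings this pipeline was
designed for, so this module fabricates them: 12 built-in exercises defined
as small sets of key poses on a canonical skeleton, piecewise-linearly
interpolated (with per-frame bone-length renormalization so segment lengths
stay anatomically constant), plus the perturbations used in robustness
testing — slower speed, mid-exercise pauses, rotated facing orientation,
sensor noise and subject height scaling.

All randomness flows from explicit seeds; identical seeds give identical
datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .features import JOINT_NAMES, SEGMENTS, SkeletonFrame

__all__ = [
    "ExerciseSpec",
    "GenerationConfig",
    "TrajectoryRecord",
    "neutral_pose",
    "builtin_exercises",
    "interpolate_poses",
    "perturb",
    "generate_trajectory",
    "generate_dataset",
]

_JIDX = {name: i for i, name in enumerate(JOINT_NAMES)}

# Upper-body joints moved together by trunk bends/twists.
_UPPER = [
    "spine", "shoulder_center", "head",
    "shoulder_left", "elbow_left", "wrist_left", "hand_left",
    "shoulder_right", "elbow_right", "wrist_right", "hand_right",
]

_ARM_CHAIN = {
    "left": ("shoulder_left", "elbow_left", "wrist_left", "hand_left"),
    "right": ("shoulder_right", "elbow_right", "wrist_right", "hand_right"),
}
_LEG_CHAIN = {
    "left": ("hip_left", "knee_left", "ankle_left", "foot_left"),
    "right": ("hip_right", "knee_right", "ankle_right", "foot_right"),
}

_UPPER_ARM = 0.28
_FOREARM = 0.25
_HAND = 0.08
_THIGH = 0.42
_SHANK = 0.40
_FOOT = 0.15


def neutral_pose() -> np.ndarray:
    """Canonical standing skeleton, (20, 3), meters; +y up, +z toward sensor."""
    j = np.zeros((len(JOINT_NAMES), 3))

    def put(name, x, y, z):
        j[_JIDX[name]] = (x, y, z)

    put("hip_center", 0.0, 1.00, 0.0)
    put("spine", 0.0, 1.12, 0.0)
    put("shoulder_center", 0.0, 1.45, 0.0)
    put("head", 0.0, 1.64, 0.0)
    for side, sx in (("left", 1.0), ("right", -1.0)):
        put(f"shoulder_{side}", sx * 0.19, 1.42, 0.0)
        put(f"elbow_{side}", sx * 0.21, 1.42 - _UPPER_ARM, 0.0)
        put(f"wrist_{side}", sx * 0.21, 1.42 - _UPPER_ARM - _FOREARM, 0.0)
        put(f"hand_{side}", sx * 0.21, 1.42 - _UPPER_ARM - _FOREARM - _HAND, 0.0)
        put(f"hip_{side}", sx * 0.10, 0.96, 0.0)
        put(f"knee_{side}", sx * 0.11, 0.96 - _THIGH, 0.0)
        put(f"ankle_{side}", sx * 0.11, 0.96 - _THIGH - _SHANK, 0.0)
        put(f"foot_{side}", sx * 0.11, 0.96 - _THIGH - _SHANK - 0.04, _FOOT)
    return j


def _set_arm(j: np.ndarray, side: str, direction) -> None:
    """Point a straight arm from the shoulder along ``direction``."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    shoulder, elbow, wrist, hand = _ARM_CHAIN[side]
    s = j[_JIDX[shoulder]]
    j[_JIDX[elbow]] = s + _UPPER_ARM * d
    j[_JIDX[wrist]] = s + (_UPPER_ARM + _FOREARM) * d
    j[_JIDX[hand]] = s + (_UPPER_ARM + _FOREARM + _HAND) * d


def _raise_knee(j: np.ndarray, side: str) -> None:
    """Thigh horizontal forward, shank hanging vertically."""
    hip, knee, ankle, foot = _LEG_CHAIN[side]
    h = j[_JIDX[hip]]
    j[_JIDX[knee]] = h + np.array([0.0, 0.0, _THIGH])
    j[_JIDX[ankle]] = j[_JIDX[knee]] + np.array([0.0, -_SHANK, 0.0])
    j[_JIDX[foot]] = j[_JIDX[ankle]] + np.array([0.0, -0.04, _FOOT])


def _abduct_leg(j: np.ndarray, side: str, angle_deg: float) -> None:
    """Straight leg swung sideways by ``angle_deg`` from vertical."""
    sx = 1.0 if side == "left" else -1.0
    a = np.deg2rad(angle_deg)
    d = np.array([sx * np.sin(a), -np.cos(a), 0.0])
    hip, knee, ankle, foot = _LEG_CHAIN[side]
    h = j[_JIDX[hip]]
    j[_JIDX[knee]] = h + _THIGH * d
    j[_JIDX[ankle]] = h + (_THIGH + _SHANK) * d
    j[_JIDX[foot]] = j[_JIDX[ankle]] + np.array([0.0, -0.04, _FOOT])


def _rot(axis: str, angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _bend_trunk(j: np.ndarray, angle_deg: float) -> None:
    """Lateral trunk bend about the hip center (positive = toward +x)."""
    r = _rot("z", angle_deg)
    pivot = j[_JIDX["hip_center"]]
    for name in _UPPER:
        j[_JIDX[name]] = pivot + r @ (j[_JIDX[name]] - pivot)


def _twist_trunk(j: np.ndarray, angle_deg: float) -> None:
    """Rotate the upper body about the vertical axis through the spine."""
    r = _rot("y", angle_deg)
    pivot = j[_JIDX["spine"]]
    for name in _UPPER:
        j[_JIDX[name]] = pivot + r @ (j[_JIDX[name]] - pivot)


def _squat(j: np.ndarray, depth: float = 0.3) -> None:
    """Drop the pelvis, lean the trunk forward, knees tracking forward."""
    for name in _UPPER + ["hip_center", "hip_left", "hip_right"]:
        j[_JIDX[name]][1] -= depth
        j[_JIDX[name]][2] -= 0.06
    r = _rot("x", 25.0)  # forward trunk lean about the hip center
    pivot = j[_JIDX["hip_center"]]
    for name in _UPPER:
        j[_JIDX[name]] = pivot + r @ (j[_JIDX[name]] - pivot)
    for side in ("left", "right"):
        knee = j[_JIDX[f"knee_{side}"]]
        knee[1] -= depth * 0.3
        knee[2] += 0.24


@dataclass
class ExerciseSpec:
    """An exercise as an ordered list of key poses on the canonical subject."""

    label: str
    key_poses: list[SkeletonFrame]
    dwell_fractions: list[float] | None = None

    def __post_init__(self) -> None:
        if len(self.key_poses) < 2:
            raise ValueError("an exercise needs at least 2 key poses")
        if self.dwell_fractions is None:
            self.dwell_fractions = [1.0 / len(self.key_poses)] * len(self.key_poses)
        if len(self.dwell_fractions) != len(self.key_poses):
            raise ValueError("one dwell fraction per key pose")
        if any(d <= 0 for d in self.dwell_fractions):
            raise ValueError("dwell fractions must be positive")
        total = sum(self.dwell_fractions)
        self.dwell_fractions = [d / total for d in self.dwell_fractions]


def _spec(label: str, poses: list[np.ndarray], dwell: list[float] | None = None) -> ExerciseSpec:
    if dwell is None:
        # Characteristic (non-terminal) poses get triple dwell: subjects hold
        # the distinctive position of an exercise longer than the rest stance.
        dwell = [1.0] + [3.0] * (len(poses) - 2) + [1.0]
    return ExerciseSpec(label, [SkeletonFrame.from_array(p) for p in poses], dwell)


def builtin_exercises() -> list[ExerciseSpec]:
    """The 12 built-in coarse full-body exercises (fixture key poses)."""
    n = neutral_pose()

    def pose(*ops) -> np.ndarray:
        j = neutral_pose()
        for op in ops:
            op(j)
        return j

    up = lambda side: (lambda j: _set_arm(j, side, (0.15 if side == "left" else -0.15, 1.0, 0.0)))
    fwd = lambda side: (lambda j: _set_arm(j, side, (0.0, 0.05, 1.0)))
    lateral = lambda side: (lambda j: _set_arm(j, side, (1.0 if side == "left" else -1.0, 0.05, 0.0)))

    up_both = pose(up("left"), up("right"))
    fwd_both = pose(fwd("left"), fwd("right"))
    up_left = pose(up("left"))
    up_right = pose(up("right"))
    bend_l = pose(lambda j: _bend_trunk(j, 60.0))
    bend_r = pose(lambda j: _bend_trunk(j, -60.0))
    # marching knee raises carry the opposite arm forward for balance
    knee_l = pose(lambda j: _raise_knee(j, "left"), fwd("right"))
    knee_r = pose(lambda j: _raise_knee(j, "right"), fwd("left"))

    two_sided = [1.0, 3.0, 1.0, 3.0, 1.0]
    specs = [
        _spec("arm_raise_left", [n, up_left, n]),
        _spec("arm_raise_right", [n, up_right, n]),
        _spec("arm_raise_both", [n, up_both, n]),
        _spec("arm_raise_alternate", [n, up_left, n, up_right, n], dwell=two_sided),
        _spec("reach_forward", [n, fwd_both, n]),
        _spec("reach_then_raise", [n, fwd_both, up_both, n]),
        _spec("trunk_bend_left", [n, bend_l, n]),
        _spec("trunk_bend_right", [n, bend_r, n]),
        _spec("trunk_sway", [n, bend_l, n, bend_r, n], dwell=two_sided),
        _spec("knee_raise_left", [n, knee_l, n]),
        _spec("knee_raise_right", [n, knee_r, n]),
        _spec("knee_march", [n, knee_l, n, knee_r, n], dwell=two_sided),
    ]
    return specs


@dataclass
class GenerationConfig:
    """Knobs for one generated trajectory; identity values change nothing."""

    n_frames: int = 40
    seed: int = 0
    speed_factor: float = 1.0
    pause_spec: tuple[float, int] | None = None  # (position fraction, pause frames)
    rotation_deg: float = 0.0
    noise_sigma: float = 0.004  # meters; consumer depth-sensor jitter after temporal filtering
    height_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.speed_factor <= 0:
            raise ValueError("speed_factor must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.height_scale <= 0:
            raise ValueError("height_scale must be positive")


def _segment_lengths(arr: np.ndarray) -> np.ndarray:
    return np.array([
        np.linalg.norm(arr[_JIDX[c]] - arr[_JIDX[p]]) for p, c in SEGMENTS
    ])


def _renormalize_bones(arr: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Rebuild the tree from hip_center so segments match ``lengths``.

    SEGMENTS lists parents before children, so one forward pass suffices.
    """
    out = arr.copy()
    for k, (p, c) in enumerate(SEGMENTS):
        d = arr[_JIDX[c]] - arr[_JIDX[p]]
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            raise ValueError(f"zero-length segment {p}->{c} during interpolation")
        out[_JIDX[c]] = out[_JIDX[p]] + lengths[k] * d / norm
    return out


def interpolate_poses(
    spec: ExerciseSpec, n_frames: int, hold_frac: float = 0.8
) -> list[SkeletonFrame]:
    """Piecewise-linear interpolation through the key poses, with holds.

    Key pose i is anchored at a normalized time built from the dwell
    fractions (half of each pose's dwell on either side) and held for
    ``hold_frac`` of its dwell, centered on the anchor — subjects pause at
    the characteristic positions of an exercise, so recorded frames cluster
    there.  Between holds, joints interpolate linearly.  Every frame is
    bone-renormalized to the first key pose's segment lengths.
    """
    if n_frames < len(spec.key_poses):
        raise ValueError("n_frames must be >= number of key poses")
    if not 0.0 <= hold_frac < 1.0:
        raise ValueError("hold_frac must be in [0, 1)")
    poses = [p.as_array() for p in spec.key_poses]
    dwell = np.asarray(spec.dwell_fractions)
    anchors = np.zeros(len(poses))
    for i in range(1, len(poses)):
        anchors[i] = anchors[i - 1] + 0.5 * (dwell[i - 1] + dwell[i])
    anchors /= anchors[-1]
    half_hold = 0.5 * hold_frac * dwell / dwell.sum()
    starts = np.clip(anchors - half_hold, 0.0, 1.0)  # hold interval of pose i
    ends = np.clip(anchors + half_hold, 0.0, 1.0)
    lengths = _segment_lengths(poses[0])

    frames = []
    for t in np.linspace(0.0, 1.0, n_frames):
        i = int(np.searchsorted(ends, t, side="left"))
        i = min(i, len(poses) - 1)
        if t >= starts[i] or i == 0:  # inside pose i's hold
            arr = poses[i]
        else:  # transitioning from pose i-1 to pose i
            span = starts[i] - ends[i - 1]
            alpha = (t - ends[i - 1]) / span if span > 0 else 1.0
            arr = (1 - alpha) * poses[i - 1] + alpha * poses[i]
        frames.append(SkeletonFrame.from_array(_renormalize_bones(arr, lengths)))
    return frames


def perturb(frames: list[SkeletonFrame], config: GenerationConfig) -> list[SkeletonFrame]:
    """Apply the robustness perturbations, in a fixed order.

    1. temporal resampling by 1/speed_factor (0.5 doubles the frame count);
    2. pause insertion: the frame at the pause position repeated, plus noise;
    3. rigid rotation about the world vertical axis by ``rotation_deg``;
    4. i.i.d. Gaussian positional noise (``noise_sigma`` per coordinate);
    5. uniform scaling by ``height_scale`` about each frame's hip_center.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    arrs = [f.as_array() for f in frames]

    if config.speed_factor != 1.0:
        n = len(arrs)
        new_n = max(2, int(round(n / config.speed_factor)))
        stack = np.stack(arrs)  # (n, 20, 3)
        ts = np.linspace(0.0, n - 1.0, new_n)
        lo = np.floor(ts).astype(int)
        hi = np.minimum(lo + 1, n - 1)
        a = (ts - lo)[:, None, None]
        arrs = list((1 - a) * stack[lo] + a * stack[hi])

    if config.pause_spec is not None:
        frac, n_pause = config.pause_spec
        pos = int(round(frac * (len(arrs) - 1)))
        held = arrs[pos]
        inserts = [
            held + rng.normal(0.0, config.noise_sigma, held.shape)
            for _ in range(n_pause)
        ]
        arrs = arrs[: pos + 1] + inserts + arrs[pos + 1 :]

    if config.rotation_deg != 0.0:
        r = _rot("y", config.rotation_deg)
        arrs = [a @ r.T for a in arrs]

    if config.noise_sigma > 0.0:
        arrs = [a + rng.normal(0.0, config.noise_sigma, a.shape) for a in arrs]

    if config.height_scale != 1.0:
        hip = _JIDX["hip_center"]
        arrs = [a[hip] + config.height_scale * (a - a[hip]) for a in arrs]

    return [SkeletonFrame.from_array(a) for a in arrs]


def generate_trajectory(spec: ExerciseSpec, config: GenerationConfig) -> list[SkeletonFrame]:
    """Interpolate the exercise, then perturb it according to ``config``."""
    return perturb(interpolate_poses(spec, config.n_frames), config)


@dataclass
class TrajectoryRecord:
    label: str
    subject: int
    rep: int
    frames: list[SkeletonFrame]
    config: GenerationConfig


def _jitter_spec(spec: ExerciseSpec, rng: np.random.Generator, sigma: float) -> ExerciseSpec:
    """Per-subject anatomical idiosyncrasy: jitter every key-pose joint."""
    poses = [
        SkeletonFrame.from_array(p.as_array() + rng.normal(0.0, sigma, (len(JOINT_NAMES), 3)))
        for p in spec.key_poses
    ]
    return ExerciseSpec(spec.label, poses, list(spec.dwell_fractions))


def generate_dataset(
    specs: list[ExerciseSpec],
    n_subjects: int,
    reps: int,
    base_config: GenerationConfig | None = None,
    seed: int = 0,
    subject_offset: int = 0,
    pose_jitter_sigma: float = 0.008,
) -> list[TrajectoryRecord]:
    """Emit ``n_subjects * reps`` labeled trajectories per exercise.

    Each subject draws a height scale and a fixed key-pose jitter from the
    seeded generator; each rep additionally varies execution speed slightly.
    ``subject_offset`` shifts subject ids (and their random draws) so that a
    held-out cohort can be generated with the same seed.
    """
    if not specs:
        raise ValueError("no exercise specs given")
    if base_config is None:
        base_config = GenerationConfig()
    records: list[TrajectoryRecord] = []
    for s in range(n_subjects):
        subject = subject_offset + s
        srng = np.random.default_rng(np.random.SeedSequence((seed, subject)))
        height = float(srng.uniform(0.92, 1.08))
        subject_specs = [_jitter_spec(sp, srng, pose_jitter_sigma) for sp in specs]
        for sp in subject_specs:
            for rep in range(reps):
                speed_jitter = float(srng.uniform(0.9, 1.1))
                cfg = replace(
                    base_config,
                    seed=int(srng.integers(0, 2**31 - 1)),
                    speed_factor=base_config.speed_factor * speed_jitter,
                    height_scale=base_config.height_scale * height,
                )
                frames = generate_trajectory(sp, cfg)
                records.append(
                    TrajectoryRecord(
                        label=sp.label, subject=subject, rep=rep, frames=frames, config=cfg
                    )
                )
    return records
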