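"""Synthetic articulated motion with an SDK-like corruption model.

Ground truth is produced by forward kinematics over the dialect's bone tree:
bone directions are rest directions perturbed by C^2 splined random angle
channels, so bone lengths are constant by construction and trajectories are
twice continuously differentiable.  Corruption adds angle-dependent Gaussian
noise (growing as a bone aligns with the optical axis), transient outlier
runs, tracking-state dropouts, and optional left/right flips — every event
is recorded in a corruption log.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .skeleton import (
    OPTICAL_AXIS,
    FramePose,
    JointObservation,
    SkeletonDialect,
    TrackingState,
    get_dialect,
)

__all__ = [
    "GeneratorConfig",
    "CorruptionEvent",
    "generate_ground_truth",
    "corrupt",
    "corruption_log_to_csv",
    "read_corruption_log",
    "mirror_joint_map",
]

# Rest poses: standing figure ~2.5 m from the camera, arms spread (T-pose,
# perpendicular to the optical axis), +Y up, left = +X in camera coordinates.
_REST_POSES: dict[str, dict[str, tuple[float, float, float]]] = {
    "kinect21": {
        "SpineBase": (0.00, 0.00, 2.50),
        "SpineMid": (0.00, 0.30, 2.50),
        "SpineShoulder": (0.00, 0.56, 2.50),
        "Neck": (0.00, 0.64, 2.50),
        "Head": (0.00, 0.80, 2.50),
        "ShoulderLeft": (0.18, 0.56, 2.50),
        "ElbowLeft": (0.46, 0.56, 2.50),
        "WristLeft": (0.71, 0.56, 2.50),
        "HandLeft": (0.80, 0.56, 2.50),
        "ShoulderRight": (-0.18, 0.56, 2.50),
        "ElbowRight": (-0.46, 0.56, 2.50),
        "WristRight": (-0.71, 0.56, 2.50),
        "HandRight": (-0.80, 0.56, 2.50),
        "HipLeft": (0.09, -0.08, 2.50),
        "KneeLeft": (0.09, -0.53, 2.50),
        "AnkleLeft": (0.09, -0.95, 2.50),
        "FootLeft": (0.09, -1.06, 2.39),
        "HipRight": (-0.09, -0.08, 2.50),
        "KneeRight": (-0.09, -0.53, 2.50),
        "AnkleRight": (-0.09, -0.95, 2.50),
        "FootRight": (-0.09, -1.06, 2.39),
    },
    "nuitrack20": {
        "Waist": (0.00, 0.00, 2.50),
        "Torso": (0.00, 0.28, 2.50),
        "Neck": (0.00, 0.56, 2.50),
        "Head": (0.00, 0.72, 2.50),
        "LeftCollar": (0.06, 0.52, 2.50),
        "LeftShoulder": (0.20, 0.52, 2.50),
        "LeftElbow": (0.48, 0.52, 2.50),
        "LeftWrist": (0.73, 0.52, 2.50),
        "LeftHand": (0.82, 0.52, 2.50),
        "RightCollar": (-0.06, 0.52, 2.50),
        "RightShoulder": (-0.20, 0.52, 2.50),
        "RightElbow": (-0.48, 0.52, 2.50),
        "RightWrist": (-0.73, 0.52, 2.50),
        "RightHand": (-0.82, 0.52, 2.50),
        "LeftHip": (0.09, -0.08, 2.50),
        "LeftKnee": (0.09, -0.53, 2.50),
        "LeftAnkle": (0.09, -0.95, 2.50),
        "RightHip": (-0.09, -0.08, 2.50),
        "RightKnee": (-0.09, -0.53, 2.50),
        "RightAnkle": (-0.09, -0.95, 2.50),
    },
}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic motion generator and corruption model."""

    dialect: SkeletonDialect | str = "kinect21"
    bone_lengths: dict[str, float] | None = None   # per-class overrides (meters)
    duration: int = 300                            # frames
    frame_rate: float = 30.0                       # Hz
    n_keyframes: int = 5                           # spline keyframes (trajectory smoothness)
    motion_amplitude: float = 0.25                 # rad, per-bone angle wiggle
    root_amplitude: float = 0.30                   # m, root translation wiggle
    noise_base: float = 0.005                      # m, isotropic Gaussian sigma
    noise_axis_gain: float = 2.0                   # extra sigma as a bone aligns with +Z
    # AR(1) coefficient of the jitter across frames (marginal sigma is
    # preserved).  Depth-SDK jitter is temporally correlated; 0 gives white
    # noise.
    noise_temporal_corr: float = 0.7
    outlier_rate: float = 0.0                      # per-joint-frame run-start probability
    outlier_magnitude: float = 0.5                 # m
    outlier_max_run: int = 4                       # frames
    dropout_rate: float = 0.0                      # per-joint-frame probability
    flip_rate: float = 0.0                         # per-frame probability
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.dialect, str):
            self.dialect = get_dialect(self.dialect)
        for name in ("outlier_rate", "dropout_rate", "flip_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.duration < 1:
            raise ValueError("duration must be at least 1 frame")
        if self.bone_lengths:
            for cls, length in self.bone_lengths.items():
                if not length > 0:
                    raise ValueError(f"bone length for class {cls!r} must be > 0")
        if self.outlier_max_run < 1:
            raise ValueError("outlier_max_run must be >= 1")


@dataclass
class CorruptionEvent:
    """One injected corruption, recoverable from the log for evaluation."""

    kind: str            # outlier | dropout | flip
    joint: str           # "*" for whole-frame events
    frame_start: int
    frame_end: int       # inclusive
    magnitude: float

    @property
    def frames(self) -> range:
        return range(self.frame_start, self.frame_end + 1)


def _bone_tree(dialect: SkeletonDialect) -> list[tuple[str, str]]:
    """Edges ordered root-outward (parent before child)."""
    adj: dict[str, list[str]] = {j: [] for j in dialect.joints}
    for a, b in dialect.edges:
        adj[a].append(b)
        adj[b].append(a)
    root = dialect.joints[0]
    ordered: list[tuple[str, str]] = []
    seen = {root}
    stack = [root]
    while stack:
        parent = stack.pop()
        for child in adj[parent]:
            if child not in seen:
                seen.add(child)
                ordered.append((parent, child))
                stack.append(child)
    return ordered


def _spline_channel(
    rng: np.random.Generator, n_keyframes: int, duration_s: float, amplitude: float
) -> Callable[[np.ndarray], np.ndarray]:
    if n_keyframes < 2 or amplitude == 0.0:
        return lambda ts: np.zeros_like(ts)
    knots = np.linspace(0.0, duration_s, n_keyframes)
    values = rng.normal(0.0, amplitude, size=n_keyframes)
    return CubicSpline(knots, values, bc_type="natural")


def _rot_x(a: np.ndarray) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    zeros, ones = np.zeros_like(a), np.ones_like(a)
    return np.stack(
        [
            np.stack([ones, zeros, zeros], -1),
            np.stack([zeros, c, -s], -1),
            np.stack([zeros, s, c], -1),
        ],
        -2,
    )


def _rot_y(a: np.ndarray) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    zeros, ones = np.zeros_like(a), np.ones_like(a)
    return np.stack(
        [
            np.stack([c, zeros, s], -1),
            np.stack([zeros, ones, zeros], -1),
            np.stack([-s, zeros, c], -1),
        ],
        -2,
    )


def generate_ground_truth(
    config: GeneratorConfig,
) -> tuple[list[FramePose], dict]:
    """Smooth articulated motion with exactly constant bone lengths.

    Returns the frames plus metadata holding the true per-class bone lengths.
    """
    dialect: SkeletonDialect = config.dialect  # type: ignore[assignment]
    rest = {j: np.array(p) for j, p in _REST_POSES[dialect.name].items()}
    tree = _bone_tree(dialect)
    rng = np.random.default_rng([config.seed, 0])
    duration_s = (config.duration - 1) / config.frame_rate
    ts = np.arange(config.duration) / config.frame_rate

    # one true length per symmetry class (mirror bones share it exactly)
    edge_set = {frozenset(e) for e in dialect.edges}
    true_lengths: dict[str, float] = {}
    for cls, bones in dialect.classes.items():
        a, b = bones[0]
        length = float(np.linalg.norm(rest[b] - rest[a]))
        if config.bone_lengths and cls in config.bone_lengths:
            length = config.bone_lengths[cls]
        true_lengths[cls] = length

    root = dialect.joints[0]
    root_traj = rest[root] + np.stack(
        [
            _spline_channel(rng, config.n_keyframes, max(duration_s, 1e-9), config.root_amplitude)(ts)
            for _ in range(3)
        ],
        axis=-1,
    )

    positions: dict[str, np.ndarray] = {root: root_traj}
    for parent, child in tree:
        bone = (parent, child) if (parent, child) in set(dialect.edges) else (child, parent)
        assert frozenset(bone) in edge_set
        u = rest[child] - rest[parent]
        u = u / np.linalg.norm(u)
        length = true_lengths[dialect.bone_class(bone)]
        alpha = _spline_channel(rng, config.n_keyframes, max(duration_s, 1e-9), config.motion_amplitude)(ts)
        beta = _spline_channel(rng, config.n_keyframes, max(duration_s, 1e-9), config.motion_amplitude)(ts)
        directions = np.einsum(
            "tij,tjk,k->ti", _rot_y(beta), _rot_x(alpha), u
        )
        positions[child] = positions[parent] + length * directions

    frames = [
        FramePose(
            timestamp=float(ts[f]),
            joints={
                name: JointObservation(position=positions[name][f].copy())
                for name in dialect.joints
            },
        )
        for f in range(config.duration)
    ]
    return frames, {"true_lengths": true_lengths, "dialect": dialect.name}


def mirror_joint_map(dialect: SkeletonDialect) -> dict[str, str]:
    """Left joint -> right counterpart (and vice versa), by name convention."""
    out: dict[str, str] = {}
    for name in dialect.joints:
        if "Left" in name:
            other = name.replace("Left", "Right")
        elif "Right" in name:
            other = name.replace("Right", "Left")
        else:
            continue
        if other in dialect.joints:
            out[name] = other
    return out


def _parent_bone(dialect: SkeletonDialect) -> dict[str, tuple[str, str] | None]:
    out: dict[str, tuple[str, str] | None] = {dialect.joints[0]: None}
    for parent, child in _bone_tree(dialect):
        bone = (parent, child) if (parent, child) in set(dialect.edges) else (child, parent)
        out[child] = bone
    return out


def corrupt(
    frames: Sequence[FramePose], config: GeneratorConfig
) -> tuple[list[FramePose], list[CorruptionEvent]]:
    """Apply the SDK-like corruption model; every event is logged.

    Order: angle-scaled Gaussian noise, outlier runs, state dropouts, flips.
    The noise sigma for a joint grows with |cos(theta)| of its parent bone
    against the optical axis.
    """
    dialect: SkeletonDialect = config.dialect  # type: ignore[assignment]
    rng = np.random.default_rng([config.seed, 1])
    noisy = copy.deepcopy(list(frames))
    log: list[CorruptionEvent] = []
    n = len(noisy)
    parent_bone = _parent_bone(dialect)

    # 1. angle-dependent Gaussian noise, AR(1)-correlated across frames
    if config.noise_base > 0:
        phi = config.noise_temporal_corr
        innovation = np.sqrt(max(1.0 - phi * phi, 0.0))
        for name in dialect.joints:
            z = np.empty((n, 3))
            z[0] = rng.normal(size=3)
            for f in range(1, n):
                z[f] = phi * z[f - 1] + innovation * rng.normal(size=3)
            bone = parent_bone[name]
            for f, frame in enumerate(noisy):
                truth = frames[f]
                if bone is None:
                    cos = 0.0
                else:
                    vec = truth.position(bone[1]) - truth.position(bone[0])
                    norm = np.linalg.norm(vec)
                    cos = 0.0 if norm == 0 else abs(float(np.dot(vec, OPTICAL_AXIS)) / norm)
                sigma = config.noise_base * (1.0 + config.noise_axis_gain * cos)
                frame.joints[name].position = frame.joints[name].position + sigma * z[f]

    # 2. outlier runs
    if config.outlier_rate > 0:
        for name in dialect.joints:
            f = 0
            while f < n:
                if rng.random() < config.outlier_rate:
                    run = int(rng.integers(1, config.outlier_max_run + 1))
                    end = min(f + run - 1, n - 1)
                    direction = rng.normal(size=3)
                    direction /= np.linalg.norm(direction)
                    offset = direction * config.outlier_magnitude
                    for g in range(f, end + 1):
                        noisy[g].joints[name].position = noisy[g].joints[name].position + offset
                    log.append(
                        CorruptionEvent(
                            kind="outlier",
                            joint=name,
                            frame_start=f,
                            frame_end=end,
                            magnitude=config.outlier_magnitude,
                        )
                    )
                    f = end + 2   # leave a clean frame between runs
                else:
                    f += 1

    # 3. tracking-state dropouts
    if config.dropout_rate > 0:
        for f, frame in enumerate(noisy):
            for name in dialect.joints:
                if rng.random() < config.dropout_rate:
                    state = (
                        TrackingState.NOT_TRACKED
                        if rng.random() < 0.5
                        else TrackingState.INFERRED
                    )
                    frame.joints[name].state = state
                    log.append(
                        CorruptionEvent(
                            kind="dropout", joint=name, frame_start=f, frame_end=f, magnitude=0.0
                        )
                    )

    # 4. left/right flips
    if config.flip_rate > 0:
        mirror = mirror_joint_map(dialect)
        left_joints = [j for j in mirror if "Left" in j]
        for f, frame in enumerate(noisy):
            if rng.random() < config.flip_rate:
                for lj in left_joints:
                    rj = mirror[lj]
                    frame.joints[lj].position, frame.joints[rj].position = (
                        frame.joints[rj].position,
                        frame.joints[lj].position,
                    )
                log.append(
                    CorruptionEvent(
                        kind="flip", joint="*", frame_start=f, frame_end=f, magnitude=0.0
                    )
                )
    return noisy, log


def corruption_log_to_csv(log: Sequence[CorruptionEvent], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "kind": e.kind,
                "joint": e.joint,
                "frame_start": e.frame_start,
                "frame_end": e.frame_end,
                "magnitude": e.magnitude,
            }
            for e in log
        ],
        columns=["kind", "joint", "frame_start", "frame_end", "magnitude"],
    ).to_csv(path, index=False)


def read_corruption_log(path: str | Path) -> list[CorruptionEvent]:
    import pandas as pd

    df = pd.read_csv(path)
    return [
        CorruptionEvent(
            kind=row.kind,
            joint=row.joint,
            frame_start=int(row.frame_start),
            frame_end=int(row.frame_end),
            magnitude=float(row.magnitude),
        )
        for row in df.itertuples()
    ]
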