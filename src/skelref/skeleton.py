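"""Skeleton graph types, built-in dialects, and sequence I/O.

A skeleton is a tree of named joints connected by bones.  Two dialects are
built in: ``kinect21`` (the Kinect v2 joint set without finger tips and
thumbs) and ``nuitrack20``.  Poses live in a right-handed camera frame in
meters, with +Z along the optical axis pointing away from the camera.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "TrackingState",
    "BoneState",
    "Bone",
    "SkeletonDialect",
    "JointObservation",
    "FramePose",
    "bone_length",
    "bone_state",
    "get_dialect",
    "load_dialect",
    "read_sequence",
    "write_sequence",
    "sequence_to_csv",
    "KINECT21",
    "NUITRACK20",
]

Bone = tuple[str, str]

#: Optical axis of the camera frame (+Z points away from the camera).
OPTICAL_AXIS = np.array([0.0, 0.0, 1.0])


class TrackingState(str, Enum):
    """Per-joint confidence label emitted by depth-camera SDKs."""

    TRACKED = "tracked"
    INFERRED = "inferred"
    NOT_TRACKED = "notTracked"


class BoneState(str, Enum):
    """Tracking state of a bone, derived from its two endpoint joints."""

    TRACKED = "tracked"
    HALF_TRACKED = "halfTracked"
    NOT_TRACKED = "notTracked"


def bone_state(state_i: TrackingState, state_j: TrackingState) -> BoneState:
    """Derive a bone's state from its endpoint joint states.

    A bone is ``tracked`` when both joints are tracked, ``notTracked`` when
    neither is, and ``halfTracked`` otherwise.  ``inferred`` joints count as
    not tracked for this rule.
    """
    a = state_i == TrackingState.TRACKED
    b = state_j == TrackingState.TRACKED
    if a and b:
        return BoneState.TRACKED
    if not a and not b:
        return BoneState.NOT_TRACKED
    return BoneState.HALF_TRACKED


def _strip_side(token: str) -> str:
    for side in ("Left", "Right"):
        token = token.replace(side, "")
    return token


@dataclass(frozen=True)
class SkeletonDialect:
    """A named skeleton graph: joints, bone edges, and left/right symmetry.

    ``edges`` must form a tree over ``joints``.  ``symmetry_pairs`` lists
    mirrored bones (left, right) that share one bone-length class; bones not
    in any pair form singleton classes.
    """

    name: str
    joints: tuple[str, ...]
    edges: tuple[Bone, ...]
    symmetry_pairs: tuple[tuple[Bone, Bone], ...] = ()
    _bone_class: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        joints = set(self.joints)
        if len(joints) != len(self.joints):
            raise ValueError(f"dialect {self.name!r}: duplicate joint names")
        for a, b in self.edges:
            if a not in joints or b not in joints:
                raise ValueError(
                    f"dialect {self.name!r}: edge ({a}, {b}) references unknown joint"
                )
        g = nx.Graph(self.edges)
        g.add_nodes_from(self.joints)
        if len(self.edges) != len(self.joints) - 1 or not nx.is_connected(g):
            raise ValueError(
                f"dialect {self.name!r}: edges must form a connected tree "
                f"(|E| = |V| - 1); got {len(self.edges)} edges over "
                f"{len(self.joints)} joints"
            )
        edge_set = set(self.edges)
        seen: set[Bone] = set()
        for left, right in self.symmetry_pairs:
            if left == right:
                raise ValueError(f"dialect {self.name!r}: symmetry pair maps a bone to itself")
            for bone in (left, right):
                if bone not in edge_set:
                    raise ValueError(
                        f"dialect {self.name!r}: symmetry pair bone {bone} is not an edge"
                    )
                if bone in seen:
                    raise ValueError(
                        f"dialect {self.name!r}: bone {bone} appears in more than one symmetry pair"
                    )
                seen.add(bone)
        # class id per bone: shared for symmetry pairs, the bone's own name otherwise
        classes: dict[Bone, str] = {}
        for left, right in self.symmetry_pairs:
            la, lb = _strip_side(left[0]), _strip_side(left[1])
            ra, rb = _strip_side(right[0]), _strip_side(right[1])
            cls = f"{la}-{lb}" if (la, lb) == (ra, rb) else f"{self.bone_name(left)}|{self.bone_name(right)}"
            classes[left] = cls
            classes[right] = cls
        for bone in self.edges:
            classes.setdefault(bone, self.bone_name(bone))
        object.__setattr__(self, "_bone_class", classes)

    @staticmethod
    def bone_name(bone: Bone) -> str:
        return f"{bone[0]}-{bone[1]}"

    def bone_class(self, bone: Bone) -> str:
        """Symmetry-class identifier of a bone (shared by mirrored bones)."""
        try:
            return self._bone_class[bone]
        except KeyError:
            raise KeyError(
                f"bone {bone} is not an edge of dialect {self.name!r}"
            ) from None

    @property
    def classes(self) -> dict[str, list[Bone]]:
        """Mapping from class id to the bones it pools."""
        out: dict[str, list[Bone]] = {}
        for bone in self.edges:
            out.setdefault(self._bone_class[bone], []).append(bone)
        return out

    @property
    def n_joints(self) -> int:
        return len(self.joints)

    def joint_index(self, name: str) -> int:
        try:
            return self.joints.index(name)
        except ValueError:
            raise KeyError(f"joint {name!r} unknown to dialect {self.name!r}") from None


@dataclass
class JointObservation:
    """A single joint measurement: 3-D position (meters) plus tracking state."""

    position: np.ndarray
    state: TrackingState = TrackingState.TRACKED

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got shape {self.position.shape}")
        if self.state != TrackingState.NOT_TRACKED and not np.all(np.isfinite(self.position)):
            raise ValueError("position must be finite unless state is notTracked")


@dataclass
class FramePose:
    """One timestamped pose: a JointObservation per dialect joint."""

    timestamp: float
    joints: dict[str, JointObservation]

    def position(self, joint: str) -> np.ndarray:
        try:
            return self.joints[joint].position
        except KeyError:
            raise KeyError(f"joint {joint!r} not present in frame (dialect mismatch?)") from None

    def state(self, joint: str) -> TrackingState:
        return self.joints[joint].state

    def positions(self, order: Sequence[str]) -> np.ndarray:
        """Stack joint positions as an (n, 3) array in the given order."""
        return np.stack([self.position(name) for name in order])


def bone_length(pose: FramePose, bone: Bone) -> float:
    """Euclidean length of a bone in one frame, in meters."""
    a, b = bone
    return float(np.linalg.norm(pose.position(b) - pose.position(a)))


def bone_vector(pose: FramePose, bone: Bone) -> np.ndarray:
    a, b = bone
    return pose.position(b) - pose.position(a)


# --------------------------------------------------------------------------
# Built-in dialects
# --------------------------------------------------------------------------

def _mirrored(edges: Iterable[tuple[str, str]], left: str, right: str) -> tuple[tuple[Bone, Bone], ...]:
    pairs = []
    for a, b in edges:
        la, lb = a.format(side=left), b.format(side=left)
        ra, rb = a.format(side=right), b.format(side=right)
        pairs.append(((la, lb), (ra, rb)))
    return tuple(pairs)


_K = "kinect21"
KINECT21 = SkeletonDialect(
    name=_K,
    joints=(
        "SpineBase", "SpineMid", "SpineShoulder", "Neck", "Head",
        "ShoulderLeft", "ElbowLeft", "WristLeft", "HandLeft",
        "ShoulderRight", "ElbowRight", "WristRight", "HandRight",
        "HipLeft", "KneeLeft", "AnkleLeft", "FootLeft",
        "HipRight", "KneeRight", "AnkleRight", "FootRight",
    ),
    edges=(
        ("SpineBase", "SpineMid"),
        ("SpineMid", "SpineShoulder"),
        ("SpineShoulder", "Neck"),
        ("Neck", "Head"),
        ("SpineShoulder", "ShoulderLeft"),
        ("ShoulderLeft", "ElbowLeft"),
        ("ElbowLeft", "WristLeft"),
        ("WristLeft", "HandLeft"),
        ("SpineShoulder", "ShoulderRight"),
        ("ShoulderRight", "ElbowRight"),
        ("ElbowRight", "WristRight"),
        ("WristRight", "HandRight"),
        ("SpineBase", "HipLeft"),
        ("HipLeft", "KneeLeft"),
        ("KneeLeft", "AnkleLeft"),
        ("AnkleLeft", "FootLeft"),
        ("SpineBase", "HipRight"),
        ("HipRight", "KneeRight"),
        ("KneeRight", "AnkleRight"),
        ("AnkleRight", "FootRight"),
    ),
    symmetry_pairs=_mirrored(
        (
            ("SpineShoulder", "Shoulder{side}"),   # shoulder-to-neck
            ("Shoulder{side}", "Elbow{side}"),     # upper arm
            ("Elbow{side}", "Wrist{side}"),        # lower arm
            ("Hip{side}", "Knee{side}"),           # upper leg
            ("Knee{side}", "Ankle{side}"),         # lower leg
        ),
        left="Left",
        right="Right",
    ),
)

NUITRACK20 = SkeletonDialect(
    name="nuitrack20",
    joints=(
        "Waist", "Torso", "Neck", "Head",
        "LeftCollar", "LeftShoulder", "LeftElbow", "LeftWrist", "LeftHand",
        "RightCollar", "RightShoulder", "RightElbow", "RightWrist", "RightHand",
        "LeftHip", "LeftKnee", "LeftAnkle",
        "RightHip", "RightKnee", "RightAnkle",
    ),
    edges=(
        ("Waist", "Torso"),
        ("Torso", "Neck"),
        ("Neck", "Head"),
        ("Torso", "LeftCollar"),
        ("LeftCollar", "LeftShoulder"),
        ("LeftShoulder", "LeftElbow"),
        ("LeftElbow", "LeftWrist"),
        ("LeftWrist", "LeftHand"),
        ("Torso", "RightCollar"),
        ("RightCollar", "RightShoulder"),
        ("RightShoulder", "RightElbow"),
        ("RightElbow", "RightWrist"),
        ("RightWrist", "RightHand"),
        ("Waist", "LeftHip"),
        ("LeftHip", "LeftKnee"),
        ("LeftKnee", "LeftAnkle"),
        ("Waist", "RightHip"),
        ("RightHip", "RightKnee"),
        ("RightKnee", "RightAnkle"),
    ),
    symmetry_pairs=_mirrored(
        (
            ("{side}Collar", "{side}Shoulder"),    # shoulder-to-neck
            ("{side}Shoulder", "{side}Elbow"),     # upper arm
            ("{side}Elbow", "{side}Wrist"),        # lower arm
            ("{side}Hip", "{side}Knee"),           # upper leg
            ("{side}Knee", "{side}Ankle"),         # lower leg
        ),
        left="Left",
        right="Right",
    ),
)

_DIALECTS: dict[str, SkeletonDialect] = {
    KINECT21.name: KINECT21,
    NUITRACK20.name: NUITRACK20,
}


def get_dialect(name: str) -> SkeletonDialect:
    """Look up a built-in dialect by name."""
    try:
        return _DIALECTS[name]
    except KeyError:
        raise KeyError(
            f"unknown dialect {name!r}; built-in: {sorted(_DIALECTS)}"
        ) from None


def load_dialect(path: str | Path) -> SkeletonDialect:
    """Load a custom dialect from a JSON file.

    Expected keys: ``joints`` (list of names), ``edges`` (list of name
    pairs), optional ``symmetry_pairs`` (list of edge pairs) and ``name``.
    """
    path = Path(path)
    spec = json.loads(path.read_text())
    pairs = tuple(
        (tuple(l), tuple(r)) for l, r in spec.get("symmetry_pairs", [])
    )
    return SkeletonDialect(
        name=spec.get("name", path.stem),
        joints=tuple(spec["joints"]),
        edges=tuple(tuple(e) for e in spec["edges"]),
        symmetry_pairs=pairs,
    )


# --------------------------------------------------------------------------
# Sequence I/O (JSON Lines; one frame per line)
# --------------------------------------------------------------------------

def _frame_from_obj(obj: Mapping, dialect: SkeletonDialect, where: str) -> FramePose:
    try:
        t = float(obj["t"])
        raw_joints = obj["joints"]
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"{where}: malformed frame object ({exc})") from None
    joints: dict[str, JointObservation] = {}
    for j in raw_joints:
        name = j["name"]
        if name not in dialect.joints:
            raise ValueError(f"{where}: unknown joint {name!r} for dialect {dialect.name!r}")
        if name in joints:
            raise ValueError(f"{where}: duplicate joint {name!r}")
        joints[name] = JointObservation(
            position=np.asarray(j["p"], dtype=float),
            state=TrackingState(j["state"]),
        )
    if len(joints) != dialect.n_joints:
        raise ValueError(
            f"{where}: frame has {len(joints)} joints, dialect "
            f"{dialect.name!r} requires {dialect.n_joints}"
        )
    return FramePose(timestamp=t, joints=joints)


def read_sequence(path: str | Path, dialect: SkeletonDialect) -> list[FramePose]:
    """Read a JSON-lines skeleton sequence, validating against the dialect."""
    frames: list[FramePose] = []
    prev_t = -np.inf
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            where = f"{path}:{lineno}"
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{where}: malformed JSON ({exc.msg})") from None
            frame = _frame_from_obj(obj, dialect, where)
            if frame.timestamp <= prev_t:
                raise ValueError(
                    f"{where}: non-monotone timestamp {frame.timestamp} (previous {prev_t})"
                )
            prev_t = frame.timestamp
            frames.append(frame)
    return frames


def write_sequence(frames: Iterable[FramePose], path: str | Path) -> None:
    """Write frames as JSON lines; round-trips positions to <=1e-9 m."""
    with open(path, "w") as fh:
        for frame in frames:
            obj = {
                "t": frame.timestamp,
                "joints": [
                    {
                        "name": name,
                        "p": [float(x) for x in obs.position],
                        "state": obs.state.value,
                    }
                    for name, obs in frame.joints.items()
                ],
            }
            fh.write(json.dumps(obj) + "\n")


def sequence_to_csv(frames: Iterable[FramePose], path: str | Path) -> None:
    """Export one row per (frame, joint): t, joint, x, y, z, state."""
    import pandas as pd

    rows = [
        {
            "t": frame.timestamp,
            "joint": name,
            "x": obs.position[0],
            "y": obs.position[1],
            "z": obs.position[2],
            "state": obs.state.value,
        }
        for frame in frames
        for name, obs in frame.joints.items()
    ]
    pd.DataFrame(rows, columns=["t", "joint", "x", "y", "z", "state"]).to_csv(path, index=False)
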