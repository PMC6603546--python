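"""Forward/backward trajectory prediction, trust rules, and outlier scoring.

Joint positions are extrapolated with a second-order one-sided
finite-difference scheme from the three preceding (forward) or following
(backward) frames; the midpoint of the two is the combined prediction.  A
per-joint counter of consecutive frames with disagreeing predictions (the
k-score) feeds both outlier flagging and the refinement weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .reference import BoneReferenceTable
from .skeleton import FramePose, SkeletonDialect, TrackingState, bone_length

__all__ = [
    "TrustConfig",
    "TrustRecord",
    "Prediction",
    "forward_predict",
    "backward_predict",
    "combine_predictions",
    "resolve_prediction",
    "update_k_score",
    "flag_outlier",
    "assess_frame",
    "trust_to_csv",
]

REASON_UNTRACKED = "untracked"
REASON_LENGTH = "length_deviation"
REASON_MOTION = "motion_implausible"


@dataclass
class TrustConfig:
    """Thresholds for the trust rules and prediction adequacy.

    ``length_threshold`` (meters) bounds the allowed deviation of an observed
    bone length from its reference; ``prediction_threshold`` (meters) bounds
    the forward/backward disagreement.  ``max_speed`` caps per-joint speed in
    m/s (``default_max_speed`` is a stand-in applied to joints without an
    entry).
    """

    length_threshold: float = 0.10
    prediction_threshold: float = 0.08
    max_speed: dict[str, float] = field(default_factory=dict)
    default_max_speed: float = 4.0
    window: int = 3

    def __post_init__(self) -> None:
        if not (self.length_threshold > 0 and self.prediction_threshold > 0):
            raise ValueError("thresholds must be positive")

    def speed_cap(self, joint: str) -> float:
        return self.max_speed.get(joint, self.default_max_speed)


@dataclass
class Prediction:
    """Combined prediction for one joint at one frame."""

    position: np.ndarray | None
    adequate: bool
    fb_distance: float | None   # |f_F - f_B|, None unless both sides exist
    forward: np.ndarray | None = None
    backward: np.ndarray | None = None


@dataclass
class TrustRecord:
    """Trust assessment of one joint in one frame."""

    reliable: bool
    reasons: frozenset[str]
    k_score: int = 0
    predicted_position: np.ndarray | None = None
    fb_distance: float | None = None
    adequate: bool = True
    outlier: bool = False
    forward: np.ndarray | None = None
    backward: np.ndarray | None = None


def forward_predict(history: Sequence[np.ndarray], dt: float) -> np.ndarray:
    """Second-order extrapolation from three past positions.

    ``history`` holds positions at t-3dt, t-2dt, t-dt (oldest first); the
    one-sided three-point stencils for the first and second derivative make
    the scheme exact for componentwise polynomials of degree <= 2.
    """
    if len(history) != 3:
        raise ValueError("forward prediction needs exactly 3 history positions")
    if not dt > 0:
        raise ValueError("dt must be positive")
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in history)
    vel = (3.0 * p3 - 4.0 * p2 + p1) / (2.0 * dt)
    acc = (p3 - 2.0 * p2 + p1) / dt**2
    return p3 + vel * dt + acc * dt**2 / 2.0


def backward_predict(future: Sequence[np.ndarray], dt: float) -> np.ndarray:
    """Mirror of :func:`forward_predict` using three future positions.

    ``future`` holds positions at t+dt, t+2dt, t+3dt (nearest first).
    """
    if len(future) != 3:
        raise ValueError("backward prediction needs exactly 3 future positions")
    return forward_predict(list(future)[::-1], dt)


def combine_predictions(
    f_forward: np.ndarray, f_backward: np.ndarray, prediction_threshold: float
) -> Prediction:
    """Midpoint of the two predictions; adequate iff they agree within threshold."""
    f_forward = np.asarray(f_forward, dtype=float)
    f_backward = np.asarray(f_backward, dtype=float)
    fb = float(np.linalg.norm(f_forward - f_backward))
    return Prediction(
        position=(f_forward + f_backward) / 2.0,
        adequate=fb <= prediction_threshold,
        fb_distance=fb,
        forward=f_forward,
        backward=f_backward,
    )


def resolve_prediction(
    f_forward: np.ndarray | None,
    f_backward: np.ndarray | None,
    prediction_threshold: float,
) -> Prediction:
    """Degraded-mode wrapper: missing sides never count as inadequate.

    With one side absent the available single-sided prediction is used; with
    neither side there is no prediction at all.
    """
    if f_forward is not None and f_backward is not None:
        return combine_predictions(f_forward, f_backward, prediction_threshold)
    side = f_forward if f_forward is not None else f_backward
    if side is None:
        return Prediction(position=None, adequate=True, fb_distance=None)
    side = np.asarray(side, dtype=float)
    return Prediction(
        position=side, adequate=True, fb_distance=None,
        forward=f_forward, backward=f_backward,
    )


def update_k_score(k_prev: int, adequate: bool) -> int:
    """Consecutive-inadequacy counter: increment on disagreement, else reset."""
    if k_prev < 0:
        raise ValueError("k_prev must be >= 0")
    return 0 if adequate else k_prev + 1


def flag_outlier(k_prev: int | None, k_cur: int, k_next: int | None) -> bool:
    """A frame is surely an outlier iff its k-score strictly exceeds both neighbors'.

    Missing neighbors (sequence boundaries) are treated as +inf, so boundary
    frames are never flagged.
    """
    if k_prev is None or k_next is None:
        return False
    return k_cur > k_prev and k_cur > k_next


def assess_frame(
    frame: FramePose,
    refs: BoneReferenceTable,
    predictions: Mapping[str, Prediction],
    dialect: SkeletonDialect,
    config: TrustConfig | None = None,
    dt: float | None = None,
) -> dict[str, TrustRecord]:
    """Apply the three trust rules to every joint of a frame.

    1. joints not tracked by the SDK are unreliable;
    2. a bone whose length deviates from its reference by more than the
       length threshold marks both endpoint joints unreliable;
    3. a joint further from its prediction than its speed cap allows over
       ``dt`` is unreliable (skipped without a prediction or ``dt``).
    """
    config = config or TrustConfig()
    reasons: dict[str, set[str]] = {name: set() for name in dialect.joints}

    for name in dialect.joints:
        if frame.state(name) != TrackingState.TRACKED:
            reasons[name].add(REASON_UNTRACKED)

    for bone in dialect.edges:
        ref = refs.reference_for(bone, dialect)
        if abs(bone_length(frame, bone) - ref) > config.length_threshold:
            reasons[bone[0]].add(REASON_LENGTH)
            reasons[bone[1]].add(REASON_LENGTH)

    for name in dialect.joints:
        pred = predictions.get(name)
        if pred is None or pred.position is None or dt is None:
            continue
        limit = config.speed_cap(name) * dt
        if np.linalg.norm(frame.position(name) - pred.position) > limit:
            reasons[name].add(REASON_MOTION)

    records: dict[str, TrustRecord] = {}
    for name in dialect.joints:
        pred = predictions.get(name)
        records[name] = TrustRecord(
            reliable=not reasons[name],
            reasons=frozenset(reasons[name]),
            predicted_position=None if pred is None else pred.position,
            fb_distance=None if pred is None else pred.fb_distance,
            adequate=True if pred is None else pred.adequate,
            forward=None if pred is None else pred.forward,
            backward=None if pred is None else pred.backward,
        )
    return records


def trust_to_csv(
    trust: Sequence[Mapping[str, TrustRecord]], path: str | Path
) -> None:
    """Export per-(frame, joint) trust records as CSV."""
    import pandas as pd

    rows = []
    for idx, records in enumerate(trust):
        for joint, rec in records.items():
            p = rec.predicted_position
            rows.append(
                {
                    "frame": idx,
                    "joint": joint,
                    "reliable": rec.reliable,
                    "reasons": "|".join(sorted(rec.reasons)),
                    "k_score": rec.k_score,
                    "fb_distance": np.nan if rec.fb_distance is None else rec.fb_distance,
                    "outlier": rec.outlier,
                    "px": np.nan if p is None else p[0],
                    "py": np.nan if p is None else p[1],
                    "pz": np.nan if p is None else p[2],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
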