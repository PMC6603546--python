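"""Reference bone-length estimation from an initialization window.

Per symmetry class (mirrored bones pooled), a first reference length is the
angle-confidence-weighted mean of the observed lengths; a second pass
down-weights observations that deviate from that first estimate and scales
by the bone tracking state.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .skeleton import (
    OPTICAL_AXIS,
    BoneState,
    FramePose,
    SkeletonDialect,
    bone_state,
    bone_vector,
)

__all__ = [
    "InitConfig",
    "ClassReference",
    "BoneReferenceTable",
    "angle_weight",
    "deviation_weight",
    "initial_reference_lengths",
    "refined_reference_lengths",
    "estimate_references",
]

log = logging.getLogger(__name__)


@dataclass
class InitConfig:
    """Parameters of the initialization window.

    ``deviation_ratio_cap`` is the relative deviation at which the second-pass
    weight reaches zero; ``t_half`` is the factor applied to half-tracked
    bones.
    """

    n_init_frames: int = 100
    deviation_ratio_cap: float = 0.5
    t_half: float = 0.8
    # Number of deviation-reweighting passes.  The first pass weights against
    # the angle-weighted initial estimate; further passes reweight against
    # the latest estimate, washing out outlier contamination of the initial.
    n_refine_passes: int = 3

    def __post_init__(self) -> None:
        if self.n_init_frames < 4:
            raise ValueError("n_init_frames must be >= 4")
        if self.n_refine_passes < 1:
            raise ValueError("n_refine_passes must be >= 1")
        if not self.deviation_ratio_cap > 0:
            raise ValueError("deviation_ratio_cap must be > 0")
        if not 0.0 <= self.t_half <= 1.0:
            raise ValueError("t_half must lie in [0, 1]")


@dataclass
class ClassReference:
    """Reference lengths of one bone symmetry class."""

    l_ref_initial: float
    l_ref_final: float | None = None
    n_observations: int = 0
    effective_weight_sum: float = 0.0

    @property
    def reference(self) -> float:
        """The length used downstream: final if available, else initial."""
        return self.l_ref_final if self.l_ref_final is not None else self.l_ref_initial


@dataclass
class BoneReferenceTable:
    """Per-symmetry-class reference bone lengths."""

    classes: dict[str, ClassReference] = field(default_factory=dict)

    def reference_for(self, bone, dialect: SkeletonDialect) -> float:
        return self.classes[dialect.bone_class(bone)].reference

    def to_json(self, path: str | Path) -> None:
        payload = {
            cls: {
                "l_ref_initial": ref.l_ref_initial,
                "l_ref_final": ref.l_ref_final,
                "n_observations": ref.n_observations,
                "effective_weight_sum": ref.effective_weight_sum,
            }
            for cls, ref in self.classes.items()
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "BoneReferenceTable":
        payload = json.loads(Path(path).read_text())
        return cls(
            classes={
                name: ClassReference(
                    l_ref_initial=entry["l_ref_initial"],
                    l_ref_final=entry.get("l_ref_final"),
                    n_observations=entry.get("n_observations", 0),
                    effective_weight_sum=entry.get("effective_weight_sum", 0.0),
                )
                for name, entry in payload.items()
            }
        )


def angle_weight(bone_direction: np.ndarray, optical_axis: np.ndarray = OPTICAL_AXIS) -> float:
    """Confidence 1 - |cos(theta)| of a length observation.

    ``theta`` is the angle between the bone direction and the camera's
    optical axis: bones parallel to the axis get weight 0, perpendicular
    ones weight 1.  A zero-length bone is degenerate and gets weight 0.
    """
    d = np.asarray(bone_direction, dtype=float)
    a = np.asarray(optical_axis, dtype=float)
    nd = np.linalg.norm(d)
    na = np.linalg.norm(a)
    if na == 0.0:
        raise ValueError("optical axis must be nonzero")
    if nd == 0.0:
        log.debug("zero-length bone direction: angle weight set to 0")
        return 0.0
    cos = float(np.dot(d, a) / (nd * na))
    return 1.0 - min(abs(cos), 1.0)


def _t_factor(state: BoneState, config: InitConfig) -> float:
    if state == BoneState.TRACKED:
        return 1.0
    if state == BoneState.NOT_TRACKED:
        return 0.0
    return config.t_half


def deviation_weight(
    l_obs: float, l_ref: float, state: BoneState, config: InitConfig | None = None
) -> float:
    """Second-pass weight of a length observation.

    ``T * max(0, 1 - (d / l_ref) / cap)`` with ``d = |l_obs - l_ref|`` and
    ``T`` in {1, t_half, 0} by bone tracking state.  Zero whenever the
    relative deviation exceeds the cap (default 0.5).
    """
    config = config or InitConfig()
    if not l_ref > 0:
        raise ValueError("l_ref must be positive")
    ratio = abs(l_obs - l_ref) / l_ref
    base = max(0.0, 1.0 - ratio / config.deviation_ratio_cap)
    return _t_factor(state, config) * base


def _pooled_observations(
    frames: Sequence[FramePose], dialect: SkeletonDialect
) -> dict[str, list[tuple[float, float, BoneState]]]:
    """Per class: (length, angle weight, bone state) for every pooled bone/frame."""
    out: dict[str, list[tuple[float, float, BoneState]]] = {
        cls: [] for cls in dialect.classes
    }
    for frame in frames:
        for bone in dialect.edges:
            vec = bone_vector(frame, bone)
            length = float(np.linalg.norm(vec))
            w = angle_weight(vec)
            st = bone_state(frame.state(bone[0]), frame.state(bone[1]))
            out[dialect.bone_class(bone)].append((length, w, st))
    return out


def initial_reference_lengths(
    frames: Sequence[FramePose],
    dialect: SkeletonDialect,
    config: InitConfig | None = None,
) -> BoneReferenceTable:
    """First-pass reference lengths: angle-weighted means per symmetry class."""
    config = config or InitConfig()
    if len(frames) < 4:
        raise ValueError("need at least 4 frames to estimate reference lengths")
    table = BoneReferenceTable()
    for cls, obs in _pooled_observations(frames, dialect).items():
        lengths = np.array([o[0] for o in obs])
        weights = np.array([o[1] for o in obs])
        total = weights.sum()
        if total <= 0.0:
            raise ValueError(
                f"bone class {cls!r}: all angle weights are zero "
                "(bone never off-axis in the initialization window)"
            )
        table.classes[cls] = ClassReference(
            l_ref_initial=float(np.dot(weights, lengths) / total),
            n_observations=len(obs),
            effective_weight_sum=float(total),
        )
    return table


def refined_reference_lengths(
    frames: Sequence[FramePose],
    table: BoneReferenceTable,
    dialect: SkeletonDialect,
    config: InitConfig | None = None,
) -> BoneReferenceTable:
    """Second-pass references: deviation- and state-weighted means.

    Classes whose every weight is zero keep their initial reference (with a
    logged warning) instead of raising.
    """
    config = config or InitConfig()
    for cls, obs in _pooled_observations(frames, dialect).items():
        ref = table.classes[cls]
        if ref is None or ref.l_ref_initial is None:
            raise ValueError(f"bone class {cls!r}: initial reference missing")
        lengths = np.array([o[0] for o in obs])
        estimate = ref.l_ref_initial
        total = 0.0
        for _ in range(config.n_refine_passes):
            weights = np.array(
                [deviation_weight(l, estimate, st, config) for l, _, st in obs]
            )
            total = weights.sum()
            if total <= 0.0:
                log.warning(
                    "bone class %r: all deviation weights zero; "
                    "falling back to the previous estimate",
                    cls,
                )
                break
            estimate = float(np.dot(weights, lengths) / total)
        ref.l_ref_final = estimate
        ref.effective_weight_sum = float(total)
    return table


def estimate_references(
    frames: Sequence[FramePose],
    dialect: SkeletonDialect,
    config: InitConfig | None = None,
) -> BoneReferenceTable:
    """Run both passes on the first ``n_init_frames`` frames."""
    config = config or InitConfig()
    window = frames[: config.n_init_frames]
    table = initial_reference_lengths(window, dialect, config)
    return refined_reference_lengths(window, table, dialect, config)
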