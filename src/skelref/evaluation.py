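"""Diagnostics: bone-length variance, prediction disagreement, symmetry error,
and ground-truth recovery metrics for synthetic runs.

All metrics are pure functions of their inputs.  Variances are population
variances over frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .prediction import TrustRecord, backward_predict, forward_predict
from .refinement import MAX_RECOVERABLE_RUN, RefinedSequence, UnrecoveredStretch
from .skeleton import FramePose, SkeletonDialect, bone_length
from .synthetic import CorruptionEvent

__all__ = [
    "bone_length_variance",
    "fb_distance_series",
    "prediction_residual_series",
    "symmetry_error",
    "ground_truth_metrics",
    "EvaluationReport",
    "evaluate",
]


def bone_length_variance(
    frames: Sequence[FramePose], dialect: SkeletonDialect
) -> tuple[dict[str, float], float]:
    """Population variance of each bone's length series, plus the total."""
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to compute a variance")
    per_bone: dict[str, float] = {}
    for bone in dialect.edges:
        series = np.array([bone_length(f, bone) for f in frames])
        per_bone[dialect.bone_name(bone)] = float(np.var(series))
    return per_bone, float(sum(per_bone.values()))


def _dt(frames: Sequence[FramePose]) -> float:
    steps = np.diff([f.timestamp for f in frames])
    return float(np.median(steps))


def fb_distance_series(
    frames: Sequence[FramePose], dialect: SkeletonDialect
) -> np.ndarray:
    """Per frame, the summed forward/backward prediction disagreement (meters).

    Boundary frames (first and last three) have no two-sided prediction and
    are reported as NaN.
    """
    n = len(frames)
    out = np.full(n, np.nan)
    if n < 7:
        return out
    dt = _dt(frames)
    for t in range(3, n - 3):
        total = 0.0
        for name in dialect.joints:
            ff = forward_predict([frames[s].position(name) for s in (t - 3, t - 2, t - 1)], dt)
            fb = backward_predict([frames[s].position(name) for s in (t + 1, t + 2, t + 3)], dt)
            total += float(np.linalg.norm(ff - fb))
        out[t] = total
    return out


def prediction_residual_series(
    frames: Sequence[FramePose], dialect: SkeletonDialect
) -> np.ndarray:
    """Per frame, the summed distance between each joint and its combined prediction."""
    n = len(frames)
    out = np.full(n, np.nan)
    if n < 7:
        return out
    dt = _dt(frames)
    for t in range(3, n - 3):
        total = 0.0
        for name in dialect.joints:
            ff = forward_predict([frames[s].position(name) for s in (t - 3, t - 2, t - 1)], dt)
            fb = backward_predict([frames[s].position(name) for s in (t + 1, t + 2, t + 3)], dt)
            total += float(np.linalg.norm(frames[t].position(name) - (ff + fb) / 2.0))
        out[t] = total
    return out


def symmetry_error(
    frames: Sequence[FramePose], dialect: SkeletonDialect
) -> dict[str, float]:
    """Per symmetry pair, the mean |l_left - l_right| over frames (meters)."""
    if not frames:
        raise ValueError("need at least 1 frame")
    out: dict[str, float] = {}
    for left, right in dialect.symmetry_pairs:
        diffs = [abs(bone_length(f, left) - bone_length(f, right)) for f in frames]
        key = f"{dialect.bone_name(left)}|{dialect.bone_name(right)}"
        out[key] = float(np.mean(diffs))
    return out


def _joint_errors(
    frames: Sequence[FramePose], truth: Sequence[FramePose], dialect: SkeletonDialect
) -> np.ndarray:
    if len(frames) != len(truth):
        raise ValueError("sequences must have equal length")
    return np.array(
        [
            [
                float(np.linalg.norm(f.position(name) - g.position(name)))
                for name in dialect.joints
            ]
            for f, g in zip(frames, truth)
        ]
    )


def ground_truth_metrics(
    refined: RefinedSequence | Sequence[FramePose],
    truth: Sequence[FramePose],
    corruption_log: Sequence[CorruptionEvent] | None = None,
    dialect: SkeletonDialect | None = None,
) -> dict:
    """Recovery metrics against the generator's ground truth.

    When ``refined`` is a :class:`RefinedSequence`, its trust records are
    used for outlier-detection precision/recall against the corruption log,
    and injected runs longer than the recoverable limit are checked against
    the pipeline's unrecovered flags.
    """
    trust: list[Mapping[str, TrustRecord]] | None = None
    unrecovered: list[UnrecoveredStretch] = []
    if isinstance(refined, RefinedSequence):
        dialect = refined.dialect
        trust = refined.trust
        unrecovered = refined.unrecovered
        frames = refined.frames
    else:
        if dialect is None:
            raise ValueError("dialect required when refined is a plain frame list")
        frames = list(refined)

    errors = _joint_errors(frames, truth, dialect)
    report: dict = {
        "mean_joint_error": float(errors.mean()),
        "max_joint_error": float(errors.max()),
    }

    if corruption_log is not None:
        outlier_events = [e for e in corruption_log if e.kind == "outlier"]
        injected = {
            (e.joint, f) for e in outlier_events for f in e.frames if f < len(frames)
        }
        if trust is not None:
            detected = {
                (name, t)
                for t, records in enumerate(trust)
                for name, rec in records.items()
                if not rec.reliable
            }
            tp = len(injected & detected)
            report["outlier_precision"] = tp / len(detected) if detected else 1.0
            report["outlier_recall"] = tp / len(injected) if injected else 1.0
        runs = []
        flagged = {(s.joint, f) for s in unrecovered for f in range(s.start, s.end + 1)}
        for e in outlier_events:
            run_errors = errors[
                [f for f in e.frames if f < len(frames)],
                dialect.joint_index(e.joint),
            ]
            runs.append(
                {
                    "joint": e.joint,
                    "frame_start": e.frame_start,
                    "frame_end": e.frame_end,
                    "length": e.frame_end - e.frame_start + 1,
                    "max_refined_error": float(run_errors.max()) if run_errors.size else np.nan,
                    "recovered": bool(run_errors.size)
                    and float(run_errors.max()) < e.magnitude / 2.0,
                    "flagged_unrecovered": any((e.joint, f) in flagged for f in e.frames),
                    "expected_recoverable": (e.frame_end - e.frame_start + 1)
                    <= MAX_RECOVERABLE_RUN,
                }
            )
        report["outlier_runs"] = runs
    return report


@dataclass
class EvaluationReport:
    """Before/after diagnostics for a refinement run."""

    bone_variance_input: dict[str, float]
    bone_variance_refined: dict[str, float]
    total_variance_input: float
    total_variance_refined: float
    symmetry_error_input: dict[str, float]
    symmetry_error_refined: dict[str, float]
    fb_distance_input_total: float
    fb_distance_refined_total: float
    prediction_residual_input_total: float
    prediction_residual_refined_total: float
    ground_truth: dict | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=float))


def evaluate(
    noisy: Sequence[FramePose],
    refined: RefinedSequence | Sequence[FramePose],
    dialect: SkeletonDialect,
    truth: Sequence[FramePose] | None = None,
    corruption_log: Sequence[CorruptionEvent] | None = None,
) -> EvaluationReport:
    """Assemble the full before/after report."""
    refined_frames = refined.frames if isinstance(refined, RefinedSequence) else list(refined)
    var_in, total_in = bone_length_variance(noisy, dialect)
    var_out, total_out = bone_length_variance(refined_frames, dialect)
    fb_in = fb_distance_series(noisy, dialect)
    fb_out = fb_distance_series(refined_frames, dialect)
    res_in = prediction_residual_series(noisy, dialect)
    res_out = prediction_residual_series(refined_frames, dialect)
    gt = None
    if truth is not None:
        gt = ground_truth_metrics(refined, truth, corruption_log, dialect)
    return EvaluationReport(
        bone_variance_input=var_in,
        bone_variance_refined=var_out,
        total_variance_input=total_in,
        total_variance_refined=total_out,
        symmetry_error_input=symmetry_error(noisy, dialect),
        symmetry_error_refined=symmetry_error(refined_frames, dialect),
        fb_distance_input_total=float(np.nansum(fb_in)),
        fb_distance_refined_total=float(np.nansum(fb_out)),
        prediction_residual_input_total=float(np.nansum(res_in)),
        prediction_residual_refined_total=float(np.nansum(res_out)),
        ground_truth=gt,
    )
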