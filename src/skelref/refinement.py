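"""Per-frame constrained energy minimization and the streaming pipeline.

Each frame is refined by minimizing

    E = lambda1 * E1 + lambda2 * E2

over all joint coordinates, where E1 anchors the candidate pose to the
observation and to the combined forward/backward prediction (balanced by the
k-score-derived weights u and w = 1 - u), and E2 penalizes squared
deviations of candidate bone lengths from their per-class reference lengths.
The pipeline is causal with a three-frame delay: a frame is refined once the
three following frames have been ingested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .prediction import (
    REASON_LENGTH,
    REASON_UNTRACKED,
    Prediction,
    TrustConfig,
    TrustRecord,
    assess_frame,
    backward_predict,
    flag_outlier,
    forward_predict,
    resolve_prediction,
    update_k_score,
)
from .reference import BoneReferenceTable, InitConfig, estimate_references
from .skeleton import FramePose, JointObservation, SkeletonDialect

__all__ = [
    "EnergyConfig",
    "RefinedFrame",
    "RefinedSequence",
    "UnrecoveredStretch",
    "joint_weights",
    "energy",
    "refine_frame",
    "refine_sequence",
    "StreamingRefiner",
]

_EPS = 1e-12          # guards bone-length gradient at coincident joints
MAX_RECOVERABLE_RUN = 4   # consecutive inadequate frames beyond which a stretch is unrecovered


@dataclass
class EnergyConfig:
    """Weights and solver settings for the per-frame energy minimization."""

    lambda1: float = 0.2
    lambda2: float = 8.25
    sigma: float = 3.0
    gtol: float = 1e-6
    max_iterations: int = 500
    # Weight direction.  With swap_uw=True (default) a joint with a clean
    # prediction history (k = 0) is anchored to its observation and the
    # prediction takes over as k grows; swap_uw=False anchors k = 0 joints to
    # the prediction instead.  The False direction closes an extrapolation
    # feedback loop whose characteristic roots lie on the unit circle, so
    # noise excites sustained oscillations in streaming mode; it is kept as
    # an escape hatch only.
    swap_uw: bool = True

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda1 and lambda2 must be >= 0")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")


def joint_weights(k: int, sigma: float = 3.0) -> tuple[float, float]:
    """Prediction/observation balance from the k-score.

    Returns ``(u, w)`` with ``u = exp(-k^2 / (2 sigma^2))`` and
    ``w = 1 - u``; joints with a clean prediction history (k = 0) are fully
    anchored to the prediction.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    u = math.exp(-(k * k) / (2.0 * sigma * sigma))
    return u, 1.0 - u


def _edge_arrays(dialect: SkeletonDialect, refs: BoneReferenceTable):
    idx_i = np.array([dialect.joint_index(a) for a, _ in dialect.edges])
    idx_j = np.array([dialect.joint_index(b) for _, b in dialect.edges])
    ref_l = np.array([refs.reference_for(bone, dialect) for bone in dialect.edges])
    return idx_i, idx_j, ref_l


def _energy_terms(
    vhat: np.ndarray,
    observed: np.ndarray,
    predicted: np.ndarray,
    u: np.ndarray,
    w: np.ndarray,
    idx_i: np.ndarray,
    idx_j: np.ndarray,
    ref_l: np.ndarray,
) -> tuple[float, float, np.ndarray]:
    """(E1, E2, grad of lambda-free terms stacked) for an (n, 3) candidate."""
    has_pred = np.isfinite(predicted).all(axis=1)
    dv = vhat - observed
    e1 = float(np.sum(w * np.sum(dv * dv, axis=1)))
    grad1 = 2.0 * w[:, None] * dv
    dp = np.where(has_pred[:, None], vhat - np.nan_to_num(predicted), 0.0)
    e1 += float(np.sum(u * np.sum(dp * dp, axis=1)))
    grad1 += 2.0 * u[:, None] * dp

    bone_vec = vhat[idx_j] - vhat[idx_i]
    lengths = np.sqrt(np.sum(bone_vec * bone_vec, axis=1))
    diff = lengths - ref_l
    e2 = float(np.sum(diff * diff))
    coeff = 2.0 * diff / np.maximum(lengths, _EPS)
    gvec = coeff[:, None] * bone_vec
    grad2 = np.zeros_like(vhat)
    np.add.at(grad2, idx_j, gvec)
    np.add.at(grad2, idx_i, -gvec)
    return e1, e2, np.stack([grad1, grad2])


def energy(
    candidate: np.ndarray,
    observed: np.ndarray,
    predicted: np.ndarray,
    weights: tuple[np.ndarray, np.ndarray],
    refs: BoneReferenceTable,
    dialect: SkeletonDialect,
    config: EnergyConfig | None = None,
) -> tuple[float, float, float]:
    """Evaluate (E, E1, E2) for a candidate pose.

    Positions are (n, 3) arrays in dialect joint order; rows of ``predicted``
    may be NaN for joints without a prediction (their u-term is dropped).
    """
    config = config or EnergyConfig()
    u, w = (np.asarray(x, dtype=float) for x in weights)
    idx_i, idx_j, ref_l = _edge_arrays(dialect, refs)
    e1, e2, _ = _energy_terms(
        np.asarray(candidate, dtype=float),
        np.asarray(observed, dtype=float),
        np.asarray(predicted, dtype=float),
        u, w, idx_i, idx_j, ref_l,
    )
    return config.lambda1 * e1 + config.lambda2 * e2, e1, e2


@dataclass
class RefinedFrame:
    """One refined pose plus solver provenance."""

    pose: FramePose
    energy_initial: float
    energy_final: float
    e1: float
    e2: float
    u: dict[str, float]
    w: dict[str, float]
    converged: bool
    status: str
    dominant_term: str = ""


@dataclass
class UnrecoveredStretch:
    """A run of consecutive inadequate predictions too long to recover from."""

    joint: str
    start: int      # frame index of the first inadequate frame
    end: int        # frame index of the last inadequate frame (inclusive)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def refine_frame(
    frame: FramePose,
    trust: dict[str, TrustRecord],
    refs: BoneReferenceTable,
    dialect: SkeletonDialect,
    config: EnergyConfig | None = None,
) -> RefinedFrame:
    """Minimize the frame energy over all joint coordinates.

    Starts from the observation for reliable joints and from the prediction
    for unreliable ones; never raises on solver failure (the initialization
    is returned with a status flag instead).  The reported final energy is
    never above the initial one.

    Anchor weights per joint (u on the prediction term, w on the
    observation term, u + w = 1 always):

    * no prediction available: (u, w) = (0, 1);
    * observation flagged untracked or length-deviant — a known-bad
      observation is replaced by the prediction: (u, w) = (1, 0);
    * observation clean but predictions disagree: (u, w) = (0, 1) — a
      prediction declared inadequate must not displace a clean observation;
    * otherwise the k-score blend from :func:`joint_weights`, oriented by
      ``config.swap_uw`` (with ``swap_uw`` the observation weight is floored
      at its value at k = recovery limit + 1: beyond the recoverable run
      length, further failures must not increase trust in the prediction,
      and a vanishing observation anchor leaves a marginally stable
      extrapolation loop).
    """
    config = config or EnergyConfig()
    n = dialect.n_joints
    observed = frame.positions(dialect.joints)
    predicted = np.full((n, 3), np.nan)
    u = np.empty(n)
    w = np.empty(n)
    init = observed.copy()
    for idx, name in enumerate(dialect.joints):
        rec = trust[name]
        ui, wi = joint_weights(rec.k_score, config.sigma)
        if config.swap_uw:
            ui, wi = wi, ui
            w_min = joint_weights(MAX_RECOVERABLE_RUN + 1, config.sigma)[0]
            if wi < w_min:
                ui, wi = 1.0 - w_min, w_min
        if rec.predicted_position is None:
            ui, wi = 0.0, 1.0
        else:
            flagged = bool(rec.reasons & {REASON_UNTRACKED, REASON_LENGTH})
            if flagged:
                ui, wi = 1.0, 0.0
            elif config.swap_uw and not rec.adequate:
                ui, wi = 0.0, 1.0
            predicted[idx] = rec.predicted_position
            if not rec.reliable and ui > wi:
                init[idx] = rec.predicted_position
        u[idx] = ui
        w[idx] = wi

    idx_i, idx_j, ref_l = _edge_arrays(dialect, refs)

    def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
        vhat = x.reshape(n, 3)
        e1, e2, grads = _energy_terms(vhat, observed, predicted, u, w, idx_i, idx_j, ref_l)
        grad = config.lambda1 * grads[0] + config.lambda2 * grads[1]
        return config.lambda1 * e1 + config.lambda2 * e2, grad.ravel()

    e_init, _ = objective(init.ravel())
    try:
        res = minimize(
            objective,
            init.ravel(),
            jac=True,
            method="L-BFGS-B",
            options={"gtol": config.gtol, "maxiter": config.max_iterations},
        )
        solution = res.x.reshape(n, 3)
        converged = bool(res.success)
        status = str(res.message)
        e_final = float(res.fun)
    except Exception as exc:  # pragma: no cover - defensive: never crash the stream
        solution, converged, status, e_final = init, False, f"solver error: {exc}", e_init
    if e_final > e_init:   # enforce descent: fall back to the initialization
        solution, e_final = init, e_init
        status += " (kept initialization)"

    _, e1, e2 = energy(solution, observed, predicted, (u, w), refs, dialect, config)
    pose = FramePose(
        timestamp=frame.timestamp,
        joints={
            name: JointObservation(
                position=solution[idx].copy(), state=frame.joints[name].state
            )
            for idx, name in enumerate(dialect.joints)
        },
    )
    return RefinedFrame(
        pose=pose,
        energy_initial=float(e_init),
        energy_final=float(e_final),
        e1=e1,
        e2=e2,
        u={name: float(u[i]) for i, name in enumerate(dialect.joints)},
        w={name: float(w[i]) for i, name in enumerate(dialect.joints)},
        converged=converged,
        status=status,
        dominant_term="E1" if config.lambda1 * e1 >= config.lambda2 * e2 else "E2",
    )


@dataclass
class RefinedSequence:
    """Refined frames plus per-frame trust and energy provenance."""

    dialect: SkeletonDialect
    frames: list[FramePose]
    records: list[RefinedFrame]
    trust: list[dict[str, TrustRecord]]
    references: BoneReferenceTable
    unrecovered: list[UnrecoveredStretch]

    def energy_log_to_csv(self, path: str | Path) -> None:
        import pandas as pd

        rows = [
            {
                "frame": i,
                "t": rec.pose.timestamp,
                "energy_initial": rec.energy_initial,
                "energy_final": rec.energy_final,
                "e1": rec.e1,
                "e2": rec.e2,
                "dominant_term": rec.dominant_term,
                "converged": rec.converged,
            }
            for i, rec in enumerate(self.records)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


class StreamingRefiner:
    """Causal refinement with the three-frame emission delay.

    Frames are pushed one at a time; frame ``t`` is refined and emitted once
    frame ``t + 3`` has been ingested (and the reference table exists).
    Forward predictions use already-refined past poses, backward predictions
    use raw future observations.  ``finish()`` flushes the trailing frames
    with forward-only predictions and returns the assembled sequence.
    """

    WINDOW = 3

    def __init__(
        self,
        dialect: SkeletonDialect,
        energy_config: EnergyConfig | None = None,
        trust_config: TrustConfig | None = None,
        init_config: InitConfig | None = None,
        references: BoneReferenceTable | None = None,
        use_refined_past: bool = True,
    ) -> None:
        self.dialect = dialect
        self.energy_config = energy_config or EnergyConfig()
        self.trust_config = trust_config or TrustConfig()
        self.init_config = init_config or InitConfig()
        self.references = references
        self.use_refined_past = use_refined_past
        self.raw: list[FramePose] = []
        self.refined: list[FramePose] = []
        self.records: list[RefinedFrame] = []
        self.trust: list[dict[str, TrustRecord]] = []
        self.unrecovered: list[UnrecoveredStretch] = []
        self._k: dict[str, int] = {name: 0 for name in dialect.joints}
        self._run_start: dict[str, int | None] = {name: None for name in dialect.joints}
        self._dt: float | None = None
        self._finished = False

    # -- ingestion ---------------------------------------------------------

    def push(self, frame: FramePose) -> list[tuple[int, RefinedFrame]]:
        """Ingest one frame; returns the (index, refined frame) pairs emitted."""
        if self._finished:
            raise RuntimeError("refiner already finished")
        if len(frame.joints) != self.dialect.n_joints:
            raise ValueError(
                f"frame has {len(frame.joints)} joints; dialect "
                f"{self.dialect.name!r} requires {self.dialect.n_joints}"
            )
        if self.raw:
            dt = frame.timestamp - self.raw[-1].timestamp
            if dt <= 0:
                raise ValueError("timestamps must strictly increase")
            if self._dt is None:
                self._dt = dt
            elif abs(dt - self._dt) / self._dt > 0.10:
                raise ValueError(
                    f"timestamp jitter exceeds 10%: step {dt:.6f}s vs {self._dt:.6f}s "
                    "(prediction assumes near-constant time steps)"
                )
        self.raw.append(frame)
        if self.references is None and len(self.raw) >= self.init_config.n_init_frames:
            self.references = estimate_references(
                self.raw[: self.init_config.n_init_frames], self.dialect, self.init_config
            )
        return self._drain(final=False)

    def finish(self) -> RefinedSequence:
        """Flush trailing frames and return the refined sequence."""
        if not self._finished:
            if self.references is None:
                if len(self.raw) < 4:
                    raise ValueError(
                        "sequence too short: need at least 4 frames to build references"
                    )
                self.references = estimate_references(self.raw, self.dialect, self.init_config)
            self._drain(final=True)
            for name, start in self._run_start.items():
                self._close_run(name, start, len(self.raw) - 1)
            self._assign_outlier_flags()
            self._finished = True
        return RefinedSequence(
            dialect=self.dialect,
            frames=self.refined,
            records=self.records,
            trust=self.trust,
            references=self.references,
            unrecovered=self.unrecovered,
        )

    # -- properties --------------------------------------------------------

    @property
    def latency_seconds(self) -> float | None:
        """Timestamp gap between the newest ingested and newest refined frame."""
        if not self.raw or not self.refined:
            return None
        return self.raw[-1].timestamp - self.refined[-1].timestamp

    # -- internals ---------------------------------------------------------

    def _drain(self, final: bool) -> list[tuple[int, RefinedFrame]]:
        emitted: list[tuple[int, RefinedFrame]] = []
        if self.references is None:
            return emitted
        while len(self.refined) < len(self.raw):
            t = len(self.refined)
            if not final and len(self.raw) < t + 1 + self.WINDOW:
                break
            emitted.append((t, self._refine_index(t)))
        return emitted

    def _predict_joint(self, name: str, t: int) -> Prediction:
        past_source = self.refined if self.use_refined_past else self.raw
        f_forward = None
        if t >= 3 and len(past_source) >= t:
            history = [past_source[s].position(name) for s in (t - 3, t - 2, t - 1)]
            if all(np.all(np.isfinite(p)) for p in history):
                f_forward = forward_predict(history, self._dt or 1.0)
        f_backward = None
        if t + 3 < len(self.raw):
            future = [self.raw[s].position(name) for s in (t + 1, t + 2, t + 3)]
            if all(np.all(np.isfinite(p)) for p in future):
                f_backward = backward_predict(future, self._dt or 1.0)
        return resolve_prediction(
            f_forward, f_backward, self.trust_config.prediction_threshold
        )

    def _joint_suspect_raw(self, frame: FramePose, name: str) -> bool:
        """Length-deviation/untracked check of one joint in a raw frame."""
        from .skeleton import TrackingState, bone_length

        if frame.state(name) != TrackingState.TRACKED:
            return True
        for bone in self.dialect.edges:
            if name in bone:
                ref = self.references.reference_for(bone, self.dialect)
                if abs(bone_length(frame, bone) - ref) > self.trust_config.length_threshold:
                    return True
        return False

    def _select_prediction_side(self, trust, t: int) -> None:
        """For flagged joints with disagreeing predictions, anchor to the
        side whose source frames pass the length-deviation rule.

        The forward side is suspect if the joint fails the rule in any of
        the three refined history frames; the backward side if any of the
        three raw future frames fails it.  With exactly one clean side,
        that side replaces the midpoint.
        """
        for name in self.dialect.joints:
            rec = trust[name]
            if (
                rec.adequate
                or rec.forward is None
                or rec.backward is None
                or not rec.reasons & {REASON_UNTRACKED, REASON_LENGTH}
            ):
                continue
            fwd_suspect = any(
                self._joint_suspect_raw(self.refined[s], name)
                for s in range(t - 3, t)
                if 0 <= s < len(self.refined)
            )
            bwd_suspect = any(
                self._joint_suspect_raw(self.raw[s], name)
                for s in range(t + 1, t + 4)
                if s < len(self.raw)
            )
            if fwd_suspect and not bwd_suspect:
                rec.predicted_position = rec.backward
            elif bwd_suspect and not fwd_suspect:
                rec.predicted_position = rec.forward

    def _refine_index(self, t: int) -> RefinedFrame:
        frame = self.raw[t]
        predictions = {name: self._predict_joint(name, t) for name in self.dialect.joints}
        trust = assess_frame(
            frame, self.references, predictions, self.dialect, self.trust_config, self._dt
        )
        self._select_prediction_side(trust, t)
        for name in self.dialect.joints:
            pred = predictions[name]
            k = update_k_score(self._k[name], pred.adequate)
            self._k[name] = k
            trust[name].k_score = k
            if pred.adequate:
                self._close_run(name, self._run_start[name], t - 1)
                self._run_start[name] = None
            elif self._run_start[name] is None:
                self._run_start[name] = t
        record = refine_frame(frame, trust, self.references, self.dialect, self.energy_config)
        self.refined.append(record.pose)
        self.records.append(record)
        self.trust.append(trust)
        return record

    def _close_run(self, joint: str, start: int | None, end: int) -> None:
        if start is not None and end - start + 1 > MAX_RECOVERABLE_RUN:
            self.unrecovered.append(UnrecoveredStretch(joint=joint, start=start, end=end))

    def _assign_outlier_flags(self) -> None:
        n = len(self.trust)
        for name in self.dialect.joints:
            ks = [self.trust[t][name].k_score for t in range(n)]
            for t in range(n):
                k_prev = ks[t - 1] if t > 0 else None
                k_next = ks[t + 1] if t + 1 < n else None
                self.trust[t][name].outlier = flag_outlier(k_prev, ks[t], k_next)


def refine_sequence(
    frames: Sequence[FramePose],
    dialect: SkeletonDialect,
    energy_config: EnergyConfig | None = None,
    trust_config: TrustConfig | None = None,
    init_config: InitConfig | None = None,
    references: BoneReferenceTable | None = None,
    batch: bool = False,
) -> RefinedSequence:
    """Refine a whole sequence through the streaming pipeline.

    The initialization-window frames are refined retrospectively once the
    reference table exists.  ``batch=True`` disables the causal restriction
    and builds forward predictions from raw (instead of refined) past frames.
    """
    init_config = init_config or InitConfig()
    minimum = (0 if references is not None else init_config.n_init_frames) + StreamingRefiner.WINDOW
    if len(frames) <= minimum:
        raise ValueError(
            f"sequence too short: got {len(frames)} frames, need more than {minimum}"
        )
    refiner = StreamingRefiner(
        dialect,
        energy_config=energy_config,
        trust_config=trust_config,
        init_config=init_config,
        references=references,
        use_refined_past=not batch,
    )
    for frame in frames:
        refiner.push(frame)
    return refiner.finish()
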