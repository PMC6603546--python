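import copy
import math

import numpy as np
import pytest

from skelref.prediction import TrustRecord
from skelref.reference import BoneReferenceTable, ClassReference, InitConfig
from skelref.refinement import (
    EnergyConfig,
    StreamingRefiner,
    energy,
    joint_weights,
    refine_frame,
    refine_sequence,
)
from skelref.skeleton import FramePose, JointObservation
from skelref.synthetic import GeneratorConfig, corrupt, generate_ground_truth
from tests.conftest import make_frame


class TestJointWeights:
    def test_k0(self):
        u, w = joint_weights(0)
        assert u == 1.0 and w == 0.0

    def test_k3_sigma3(self):
        u, w = joint_weights(3, 3.0)
        assert u == pytest.approx(math.exp(-0.5), abs=1e-9)
        assert w == pytest.approx(1 - math.exp(-0.5), abs=1e-9)

    def test_large_k(self):
        u, w = joint_weights(30, 3.0)
        assert u == pytest.approx(0.0, abs=1e-12)
        assert w == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("k", [0, 1, 2, 5, 17])
    def test_sum_to_one(self, k):
        u, w = joint_weights(k)
        assert u + w == pytest.approx(1.0, abs=1e-15)
        assert 0.0 < u <= 1.0
        assert 0.0 <= w < 1.0

    def test_negative_k(self):
        with pytest.raises(ValueError):
            joint_weights(-1)


def _chain2_setup(obs_b=1.2, l_ref=1.0):
    dialect_refs = BoneReferenceTable(
        classes={"A-B": ClassReference(l_ref_initial=l_ref, l_ref_final=l_ref)}
    )
    frame = make_frame(0.0, {"A": [0, 0, 0], "B": [obs_b, 0, 0]})
    trust = {
        j: TrustRecord(reliable=True, reasons=frozenset(), k_score=0) for j in "AB"
    }
    return frame, trust, dialect_refs


class TestEnergy:
    def test_zero_at_perfect_candidate(self, chain2):
        _, _, refs = _chain2_setup(obs_b=1.0)
        pos = np.array([[0, 0, 0], [1.0, 0, 0]], dtype=float)
        pred = pos.copy()
        e, e1, e2 = energy(pos, pos, pred, (np.ones(2), np.zeros(2)), refs, chain2)
        assert e == pytest.approx(0.0, abs=1e-15)
        assert e1 == 0.0 and e2 == 0.0

    def test_lambda2_linearity(self, chain2):
        _, _, refs = _chain2_setup()
        cand = np.array([[0, 0, 0], [1.3, 0, 0]], dtype=float)
        obs = np.array([[0, 0, 0], [1.2, 0, 0]], dtype=float)
        pred = np.full((2, 3), np.nan)
        weights = (np.zeros(2), np.ones(2))
        e_a, _, e2_a = energy(cand, obs, pred, weights, refs, chain2, EnergyConfig(lambda2=8.25))
        e_b, _, e2_b = energy(cand, obs, pred, weights, refs, chain2, EnergyConfig(lambda2=16.5))
        assert e2_a == pytest.approx(e2_b, abs=1e-15)
        lam1 = EnergyConfig().lambda1
        assert e_b - lam1 * 0.01 == pytest.approx(2 * (e_a - lam1 * 0.01), abs=1e-12)

    def test_single_bone_term(self, chain2):
        _, _, refs = _chain2_setup(l_ref=1.0)
        cand = np.array([[0, 0, 0], [1.2, 0, 0]], dtype=float)
        pred = np.full((2, 3), np.nan)
        cfg = EnergyConfig(lambda1=0.0)
        e, e1, e2 = energy(cand, cand, pred, (np.zeros(2), np.ones(2)), refs, chain2, cfg)
        assert e == pytest.approx(cfg.lambda2 * 0.2**2, abs=1e-12)
        assert e2 == pytest.approx(0.04, abs=1e-12)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EnergyConfig(lambda1=-0.1)
        with pytest.raises(ValueError):
            EnergyConfig(sigma=0.0)


class TestRefineFrame:
    def test_two_joint_toy_reaches_reference_length(self, chain2):
        frame, trust, refs = _chain2_setup(obs_b=1.2, l_ref=1.0)
        result = refine_frame(frame, trust, refs, chain2, EnergyConfig(lambda1=0.0))
        length = np.linalg.norm(result.pose.position("B") - result.pose.position("A"))
        assert length == pytest.approx(1.0, abs=1e-4)

    def test_clean_frame_stays_put(self, chain2):
        frame, trust, refs = _chain2_setup(obs_b=1.0, l_ref=1.0)
        result = refine_frame(frame, trust, refs, chain2)
        for j in "AB":
            assert np.linalg.norm(result.pose.position(j) - frame.position(j)) < 1e-4

    def test_energy_descent(self, chain2):
        frame, trust, refs = _chain2_setup(obs_b=1.4)
        result = refine_frame(frame, trust, refs, chain2)
        assert result.energy_final <= result.energy_initial

    def test_weights_sum_to_one(self, chain3):
        refs = BoneReferenceTable(
            classes={
                "A-B": ClassReference(1.0, 1.0),
                "B-C": ClassReference(1.0, 1.0),
            }
        )
        frame = make_frame(0.0, {"A": [0, 0, 0], "B": [1, 0, 0], "C": [2, 0, 0]})
        trust = {
            "A": TrustRecord(reliable=True, reasons=frozenset(), k_score=0),
            "B": TrustRecord(
                reliable=True, reasons=frozenset(), k_score=2,
                predicted_position=np.array([1.0, 0, 0]),
            ),
            "C": TrustRecord(
                reliable=False, reasons=frozenset({"length_deviation"}), k_score=4,
                predicted_position=np.array([2.0, 0, 0]),
            ),
        }
        result = refine_frame(frame, trust, refs, chain3)
        for j in "ABC":
            assert result.u[j] + result.w[j] == pytest.approx(1.0, abs=1e-12)

    def test_rigid_equivariance(self, chain3):
        refs = BoneReferenceTable(
            classes={"A-B": ClassReference(0.5, 0.5), "B-C": ClassReference(0.3, 0.3)}
        )
        obs = {"A": [0.0, 0, 0], "B": [0.55, 0.1, -0.05], "C": [0.9, 0.1, 0.0]}
        pred = {"A": [0.02, -0.01, 0], "B": [0.5, 0.05, 0], "C": [0.82, 0.08, 0.02]}
        cfg = EnergyConfig(gtol=1e-12)

        def build(transform):
            frame = make_frame(0.0, {j: transform(np.array(obs[j])) for j in "ABC"})
            trust = {
                j: TrustRecord(
                    reliable=True, reasons=frozenset(), k_score=k,
                    predicted_position=transform(np.array(pred[j])), adequate=True,
                )
                for j, k in (("A", 2), ("B", 3), ("C", 1))
            }
            return refine_frame(frame, trust, refs, chain3, cfg)

        rng = np.random.default_rng(5)
        for _ in range(3):
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            t = rng.normal(size=3)
            plain = build(lambda x: x)
            moved = build(lambda x: q @ x + t)
            for j in "ABC":
                expected = q @ plain.pose.position(j) + t
                np.testing.assert_allclose(moved.pose.position(j), expected, atol=1e-6)


def _scenario(seed=0, duration=120, **kw):
    kw.setdefault("noise_base", 0.004)
    cfg = GeneratorConfig(duration=duration, seed=seed, **kw)
    truth, meta = generate_ground_truth(cfg)
    noisy, log = corrupt(truth, cfg)
    return cfg, truth, noisy, log, meta


class TestRefineSequence:
    def test_too_short(self, kinect):
        cfg, truth, noisy, _, _ = _scenario(duration=20, noise_base=0.0)
        with pytest.raises(ValueError, match="too short"):
            refine_sequence(noisy, kinect, init_config=InitConfig(n_init_frames=100))

    def test_noiseless_near_identity(self, kinect):
        cfg, truth, noisy, _, _ = _scenario(duration=80, noise_base=0.0)
        result = refine_sequence(noisy, kinect, init_config=InitConfig(n_init_frames=20))
        worst = max(
            np.linalg.norm(f.position(j) - g.position(j))
            for f, g in zip(result.frames, truth)
            for j in kinect.joints
        )
        assert worst < 1e-3

    def test_variance_reduced(self, kinect):
        from skelref.evaluation import bone_length_variance

        cfg, truth, noisy, _, _ = _scenario(seed=4, duration=150)
        result = refine_sequence(noisy, kinect, init_config=InitConfig(n_init_frames=50))
        _, before = bone_length_variance(noisy, kinect)
        _, after = bone_length_variance(result.frames, kinect)
        assert after < before

    def test_outlier_jump_reduced(self, kinect):
        cfg, truth, noisy, _, _ = _scenario(seed=9, duration=120)
        noisy = copy.deepcopy(noisy)
        offset = np.array([0.4, 0.2, 0.1])
        for f in (70, 71):
            noisy[f].joints["HandLeft"].position = (
                noisy[f].joints["HandLeft"].position + offset
            )
        result = refine_sequence(noisy, kinect, init_config=InitConfig(n_init_frames=40))
        in_err = max(
            np.linalg.norm(noisy[f].position("HandLeft") - truth[f].position("HandLeft"))
            for f in (70, 71)
        )
        out_err = max(
            np.linalg.norm(result.frames[f].position("HandLeft") - truth[f].position("HandLeft"))
            for f in (70, 71)
        )
        assert out_err < in_err

    def test_recovery_limit_flagged(self, kinect):
        cfg, truth, noisy, _, _ = _scenario(seed=2, duration=140)
        noisy = copy.deepcopy(noisy)
        offset = np.array([0.0, 0.45, 0.2])
        for f in range(80, 86):  # 6-frame run
            noisy[f].joints["WristRight"].position = (
                noisy[f].joints["WristRight"].position + offset
            )
        result = refine_sequence(noisy, kinect, init_config=InitConfig(n_init_frames=40))
        stretches = [
            s for s in result.unrecovered
            if s.joint == "WristRight" and s.start <= 85 and s.end >= 80
        ]
        assert stretches, "6-frame corruption must be flagged as unrecovered"

    def test_jitter_rejected(self, kinect):
        cfg, truth, noisy, _, _ = _scenario(duration=40, noise_base=0.0)
        noisy[25].timestamp += 0.02  # 60% step jitter at 30 Hz
        with pytest.raises(ValueError, match="jitter"):
            refine_sequence(noisy, kinect, init_config=InitConfig(n_init_frames=10))

    def test_energy_log_and_uw_invariant(self, kinect, tmp_path):
        cfg, truth, noisy, _, _ = _scenario(seed=6, duration=60)
        result = refine_sequence(noisy, kinect, init_config=InitConfig(n_init_frames=20))
        for rec in result.records:
            assert rec.energy_final <= rec.energy_initial + 1e-12
            for j in kinect.joints:
                assert rec.u[j] + rec.w[j] == pytest.approx(1.0, abs=1e-12)
        log_path = tmp_path / "energy.csv"
        result.energy_log_to_csv(log_path)
        import pandas as pd

        df = pd.read_csv(log_path)
        assert len(df) == len(result.frames)

    def test_batch_mode(self, kinect):
        cfg, truth, noisy, _, _ = _scenario(seed=8, duration=60)
        result = refine_sequence(
            noisy, kinect, init_config=InitConfig(n_init_frames=20), batch=True
        )
        assert len(result.frames) == 60

    def test_precomputed_references_reused(self, kinect):
        from skelref.reference import estimate_references

        cfg, truth, noisy, _, _ = _scenario(seed=3, duration=40)
        refs = estimate_references(noisy, kinect, InitConfig(n_init_frames=40))
        result = refine_sequence(noisy, kinect, references=refs)
        assert result.references is refs


class TestStreaming:
    def test_three_frame_delay(self, kinect):
        cfg, truth, noisy, _, _ = _scenario(duration=60, noise_base=0.002)
        refiner = StreamingRefiner(kinect, init_config=InitConfig(n_init_frames=20))
        emitted = []
        for i, frame in enumerate(noisy):
            out = refiner.push(frame)
            emitted.extend(idx for idx, _ in out)
            if i >= 20:
                # steady state: newest refined frame lags newest input by 3
                assert emitted[-1] == i - 3
                assert refiner.latency_seconds == pytest.approx(3 / 30.0, abs=1e-9)
        result = refiner.finish()
        assert len(result.frames) == 60
        assert emitted == sorted(emitted)

    def test_push_after_finish_rejected(self, kinect):
        cfg, truth, noisy, _, _ = _scenario(duration=30, noise_base=0.0)
        refiner = StreamingRefiner(kinect, init_config=InitConfig(n_init_frames=10))
        for frame in noisy:
            refiner.push(frame)
        refiner.finish()
        with pytest.raises(RuntimeError):
            refiner.push(noisy[0])

    def test_outlier_flags_assigned(self, kinect):
        cfg, truth, noisy, _, _ = _scenario(seed=12, duration=80)
        noisy = copy.deepcopy(noisy)
        noisy[50].joints["HandRight"].position = (
            noisy[50].joints["HandRight"].position + np.array([0.5, 0, 0])
        )
        result = refine_sequence(noisy, kinect, init_config=InitConfig(n_init_frames=30))
        ks = [result.trust[t]["HandRight"].k_score for t in range(80)]
        flags = [result.trust[t]["HandRight"].outlier for t in range(80)]
        for t in range(1, 79):
            expected = ks[t] > ks[t - 1] and ks[t] > ks[t + 1]
            assert flags[t] == expected
        assert flags[0] is False and flags[-1] is False
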