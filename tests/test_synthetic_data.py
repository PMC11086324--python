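"""Synthetic protocol generators: trajectories, activations, EMG, gestures."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from semg_motionmap.gesture_recognition import CLASSES
from semg_motionmap.signal_processing import sliding_features
from semg_motionmap.synthetic_data import (
    EmgNoiseModel,
    ProtocolSpec,
    SynergyMatrix,
    activation_from_trajectory,
    default_synergy,
    gen_arm_dataset,
    gen_emg,
    gen_gesture_dataset,
    gen_trajectory,
    gesture_templates,
    minimum_jerk,
)
from semg_motionmap.trajectory import DOF_NAMES


class TestProtocol:
    def test_duration_arithmetic(self):
        p = ProtocolSpec(hold_s=3, rest_s=5, reps=5, fs=1000, rise_s=1)
        assert p.rep_s == 10.0
        assert p.total_s == 50.0
        traj = gen_trajectory("elbow_flex", 90.0, p)
        assert len(traj.times) == 50000

    def test_invalid_protocol_rejected(self):
        with pytest.raises(ValueError):
            ProtocolSpec(reps=0)
        with pytest.raises(ValueError):
            ProtocolSpec(hold_s=0)

    def test_normalized_rep_time(self):
        p = ProtocolSpec()
        t = np.array([0.0, 5.0, 10.0, 15.0])
        assert np.allclose(p.normalized_rep_time(t), [0.0, 0.5, 0.0, 0.5])


class TestTrajectory:
    def test_hold_duration_and_plateau(self):
        p = ProtocolSpec()
        traj = gen_trajectory("elbow_flex", 90.0, p)
        rep = traj.angles[DOF_NAMES.index("elbow_flex"), : int(p.rep_s * p.fs)]
        # 3 s plateau plus the fall segment's first sample, which is still 90
        assert int(3 * p.fs) <= np.sum(rep == 90.0) <= int(3 * p.fs) + 1

    def test_zero_target_is_identically_zero(self):
        traj = gen_trajectory("elbow_flex", 0.0)
        assert np.all(traj.angles == 0.0)

    def test_out_of_range_target_rejected(self):
        with pytest.raises(ValueError, match="range"):
            gen_trajectory("elbow_flex", 130.0)

    def test_starts_and_ends_at_zero(self):
        traj = gen_trajectory("shoulder_abd", 60.0)
        col = traj.angles[DOF_NAMES.index("shoulder_abd")]
        assert col[0] == 0.0 and col[-1] == 0.0

    def test_minimum_jerk_endpoints(self):
        assert minimum_jerk(np.array([0.0, 1.0])) == pytest.approx([0.0, 1.0])
        # monotone on [0, 1]
        s = minimum_jerk(np.linspace(0, 1, 101))
        assert np.all(np.diff(s) >= 0)


class TestActivation:
    def test_zero_trajectory_zero_tonic(self):
        traj = gen_trajectory("elbow_flex", 0.0)
        syn = default_synergy()
        syn = SynergyMatrix(syn.matrix, np.zeros(7))
        env = activation_from_trajectory(traj, syn)
        assert np.all(env == 0.0)

    def test_tonic_only_for_still_arm(self):
        traj = gen_trajectory("elbow_flex", 0.0)
        env = activation_from_trajectory(traj)
        assert np.allclose(env, default_synergy().tonic[:, None])

    def test_phasic_component_linear_in_velocity_pre_clip(self):
        p = ProtocolSpec(reps=1)
        t1 = gen_trajectory("elbow_flex", 40.0, p)
        t2 = gen_trajectory("elbow_flex", 80.0, p)
        syn = SynergyMatrix(default_synergy().matrix, np.zeros(7))
        e1 = activation_from_trajectory(t1, syn, beta=0.0, clip=False)
        e2 = activation_from_trajectory(t2, syn, beta=0.0, clip=False)
        assert np.allclose(e2, 2.0 * e1, atol=1e-9)

    def test_hold_phase_sustained_activation(self):
        p = ProtocolSpec(reps=1)
        traj = gen_trajectory("elbow_flex", 90.0, p)
        env = activation_from_trajectory(traj)
        hold = slice(int(1.5 * p.fs), int(3.5 * p.fs))
        biceps = env[2, hold]
        assert np.all(biceps > 0.1)

    def test_envelope_bounds(self):
        traj = gen_trajectory("elbow_flex", 120.0)
        env = activation_from_trajectory(traj)
        assert np.all(env >= 0.0) and np.all(env <= 1.0)

    def test_invalid_synergy_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            SynergyMatrix(-np.ones((7, 5)), np.zeros(7))
        with pytest.raises(ValueError, match="at least one muscle"):
            SynergyMatrix(np.zeros((7, 5)), np.zeros(7))


class TestEmgGeneration:
    def test_zero_envelope_zero_noise_gives_silence(self):
        noise = EmgNoiseModel(mains_amp=0, drift_amp=0, noise_sd=0)
        rec = gen_emg(np.zeros((7, 2000)), fs=1000.0, noise=noise)
        assert np.allclose(rec.samples, 0.0)

    def test_seed_determinism(self):
        env = np.full((7, 2000), 0.4)
        r1 = gen_emg(env, 1000.0, EmgNoiseModel(seed=5))
        r2 = gen_emg(env, 1000.0, EmgNoiseModel(seed=5))
        assert np.array_equal(r1.samples, r2.samples)

    def test_incompatible_band_rejected(self):
        with pytest.raises(ValueError, match="band"):
            gen_emg(np.zeros((1, 100)), fs=200.0, noise=EmgNoiseModel(band=(20.0, 150.0)))

    def test_windowed_rms_tracks_envelope(self):
        """Rank correlation between windowed RMS of the clean modulated
        carrier and the driving envelope exceeds 0.95."""
        fs = 1000.0
        n = 20000
        t = np.arange(n) / fs
        env = (0.5 + 0.45 * np.sin(2 * np.pi * 0.2 * t))[None, :]
        rec = gen_emg(env, fs, EmgNoiseModel(mains_amp=0, drift_amp=0, noise_sd=0, seed=2))
        feats = sliding_features(rec, 250.0, 125.0, "RMS")
        idx = np.clip((feats.frame_times * fs).astype(int), 0, n - 1)
        rho = spearmanr(feats.frames[0], env[0, idx]).statistic
        assert rho > 0.95


class TestGestureDataset:
    def test_balanced_sizes(self):
        ds = gen_gesture_dataset(5, seed=1)
        assert len(ds) == 20
        for cls in CLASSES:
            assert np.sum(ds.labels == cls) == 5

    def test_seed_determinism(self):
        d1 = gen_gesture_dataset(3, overlap=0.5, seed=9)
        d2 = gen_gesture_dataset(3, overlap=0.5, seed=9)
        assert np.array_equal(d1.windows, d2.windows)

    def test_overlap_one_makes_palm_templates_identical(self):
        t = gesture_templates(1.0)
        assert np.allclose(t["palm_up"], t["palm_down"])

    @staticmethod
    def _template_oracle_accuracy(ds, overlap):
        """Nearest-template classifier on per-channel RMS envelopes."""
        templates = gesture_templates(overlap)
        correct = 0
        for w, lab in zip(ds.windows, ds.labels):
            env = np.sqrt(np.mean(w**2, axis=1))
            scores = {
                c: -np.linalg.norm(env / np.linalg.norm(env) - v / np.linalg.norm(v))
                for c, v in templates.items()
            }
            if max(scores, key=scores.get) == lab:
                correct += 1
        return correct / len(ds)

    def test_zero_overlap_oracle_separable(self):
        ds = gen_gesture_dataset(25, overlap=0.0, seed=3)
        assert self._template_oracle_accuracy(ds, 0.0) >= 0.99

    def test_full_overlap_palms_indistinguishable(self):
        ds = gen_gesture_dataset(40, overlap=1.0, seed=3)
        mask = np.isin(ds.labels, ["palm_up", "palm_down"])
        sub_correct = 0
        templates = gesture_templates(0.0)  # distinct templates vs identical data
        for w, lab in zip(ds.windows[mask], ds.labels[mask]):
            env = np.sqrt(np.mean(w**2, axis=1))
            scores = {
                c: -np.linalg.norm(env / np.linalg.norm(env) - v / np.linalg.norm(v))
                for c, v in templates.items()
                if c in ("palm_up", "palm_down")
            }
            sub_correct += max(scores, key=scores.get) == lab
        acc = sub_correct / mask.sum()
        assert 0.3 <= acc <= 0.7  # chance level between the two classes


@pytest.fixture(scope="module")
def combo():
    return gen_arm_dataset(
        [("shoulder_abd", 60.0), ("elbow_flex", 90.0), ("forearm_rot", 45.0)],
        protocol=ProtocolSpec(reps=2),
        seed=8,
    )


class TestArmDataset:
    def test_active_and_inactive_dofs(self, combo):
        abd = combo.trajectory.dof("shoulder_abd")
        assert abd.max() == pytest.approx(60.0)
        assert np.all(combo.trajectory.dof("shoulder_flex") == 0.0)
        assert np.all(combo.trajectory.dof("shoulder_rot") == 0.0)

    def test_empty_spec_gives_flat_everything(self):
        ds = gen_arm_dataset([], protocol=ProtocolSpec(reps=1), seed=0)
        assert np.all(ds.trajectory.angles == 0.0)

    def test_duplicate_dof_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            gen_arm_dataset([("elbow_flex", 30.0), ("elbow_flex", 60.0)])

    def test_quaternions_decode_to_trajectory(self, combo):
        from semg_motionmap.kinematics import angles_from_streams

        traj = angles_from_streams(
            combo.streams["base"], combo.streams["shoulder"], combo.streams["elbow"]
        )
        truth = np.stack(
            [
                np.interp(traj.times, combo.trajectory.times, combo.trajectory.angles[i])
                for i in range(5)
            ]
        )
        assert np.max(np.abs(traj.angles - truth)) < 1e-3

    def test_feature_informativeness(self, combo):
        """Per-muscle windowed RMS rank-correlates with the driving DOF's
        position+velocity drive in the low-noise limit."""
        from semg_motionmap.synthetic_data import default_synergy

        ds = gen_arm_dataset(
            [("elbow_flex", 90.0)],
            protocol=ProtocolSpec(reps=2),
            noise=EmgNoiseModel(mains_amp=0, drift_amp=0, noise_sd=0),
            seed=4,
        )
        feats = sliding_features(ds.emg, 300.0, 100.0, "RMS")
        env = activation_from_trajectory(ds.trajectory, default_synergy())
        idx = np.clip((feats.frame_times * ds.emg.fs).astype(int), 0, env.shape[1] - 1)
        rho = spearmanr(feats.frames[2], env[2, idx]).statistic  # biceps
        assert rho > 0.9
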