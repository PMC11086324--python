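"""Protocol-faithful synthetic sEMG, joint-angle and IMU data.

No public recordings exist for this kind of armband/electrode protocol, so
every downstream module is exercised on simulated data that mimics the
acquisition sessions:

* Joint trajectories follow the hold/rest protocol — a 1 s minimum-jerk
  rise from 0 deg to the target, a 3 s hold, a 1 s minimum-jerk return and
  a 5 s rest, repeated 5 times — within the per-DOF planning ranges.
* Muscle activation envelopes come from a 7 x 5 synergy matrix mapping DOF
  drive (a phasic velocity term plus a position-proportional holding term)
  to the seven recorded muscles, with a small tonic baseline.
* sEMG is the standard amplitude-modulation model: envelope x band-limited
  zero-mean Gaussian carrier, plus 50 Hz mains interference, low-frequency
  baseline drift and wide-band sensor noise.
* Gesture windows (8 x 200) are built from class-specific channel-emphasis
  templates; an ``overlap`` parameter pulls the palm_up and palm_down
  templates toward their common mean to emulate the confusability of those
  two gestures.
* IMU orientation streams are composed from the trajectory with the same
  rotation conventions the kinematics module decodes, so
  generate -> decompose round trips are exact up to numerics.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import signal as sps

from . import kinematics
from .gesture_recognition import CLASSES, GestureDataset, WINDOW_CHANNELS, WINDOW_SAMPLES
from .kinematics import OrientationStream
from .signal_processing import EmgRecording
from .trajectory import DOF_NAMES, DOF_RANGES, JointTrajectory

__all__ = [
    "MUSCLE_NAMES",
    "ProtocolSpec",
    "SynergyMatrix",
    "EmgNoiseModel",
    "ArmDataset",
    "minimum_jerk",
    "gen_trajectory",
    "activation_from_trajectory",
    "gen_emg",
    "gen_gesture_dataset",
    "gen_arm_dataset",
    "default_synergy",
]

MUSCLE_NAMES = (
    "trapezius",
    "long_head",
    "biceps",
    "triceps",
    "deltoid_ant",
    "deltoid_mid",
    "deltoid_post",
)


@dataclass
class ProtocolSpec:
    """Acquisition timing: rise 1 s, hold ``hold_s``, fall 1 s, rest ``rest_s``, x ``reps``."""

    hold_s: float = 3.0
    rest_s: float = 5.0
    reps: int = 5
    fs: float = 1000.0
    rise_s: float = 1.0

    def __post_init__(self) -> None:
        if min(self.hold_s, self.rest_s, self.rise_s) <= 0 or self.fs <= 0:
            raise ValueError("protocol durations and fs must be positive")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")

    @property
    def rep_s(self) -> float:
        return self.rise_s + self.hold_s + self.rise_s + self.rest_s

    @property
    def total_s(self) -> float:
        return self.reps * self.rep_s

    def normalized_rep_time(self, times: np.ndarray) -> np.ndarray:
        """Motion time normalised to [0, 1) within each repetition."""
        return (np.asarray(times, dtype=float) % self.rep_s) / self.rep_s


def minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on [0, 1]: 10 tau^3 - 15 tau^4 + 6 tau^5."""
    tau = np.clip(np.asarray(tau, dtype=float), 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _single_dof_profile(target: float, protocol: ProtocolSpec) -> np.ndarray:
    """One full protocol (all reps) of rise/hold/fall/rest for one DOF."""
    fs = protocol.fs
    n_rise = int(round(protocol.rise_s * fs))
    n_hold = int(round(protocol.hold_s * fs))
    n_rest = int(round(protocol.rest_s * fs))
    tau = np.arange(n_rise) / n_rise
    rise = target * minimum_jerk(tau)
    rep = np.concatenate([rise, np.full(n_hold, target), target - rise, np.zeros(n_rest)])
    return np.tile(rep, protocol.reps)


def gen_trajectory(dof: str, target_deg: float, protocol: ProtocolSpec | None = None) -> JointTrajectory:
    """Protocol trajectory for one DOF (all other DOFs stay at 0 deg)."""
    protocol = protocol or ProtocolSpec()
    if dof not in DOF_RANGES:
        raise ValueError(f"unknown DOF {dof!r}")
    lo, hi = DOF_RANGES[dof]
    if not lo <= target_deg <= hi:
        raise ValueError(f"target {target_deg} deg outside {dof} planning range [{lo}, {hi}]")
    profile = _single_dof_profile(target_deg, protocol)
    angles = np.zeros((len(DOF_NAMES), len(profile)))
    angles[DOF_NAMES.index(dof)] = profile
    times = np.arange(len(profile)) / protocol.fs
    return JointTrajectory(times=times, angles=angles)


@dataclass
class SynergyMatrix:
    """Nonnegative 7 x 5 mapping from DOF drive to muscle activation.

    ``matrix[m, d]`` is the gain from DOF ``d``'s drive to muscle ``m``;
    ``tonic`` is the per-muscle resting baseline.
    """

    matrix: np.ndarray
    tonic: np.ndarray
    muscle_names: tuple[str, ...] = MUSCLE_NAMES

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.tonic = np.asarray(self.tonic, dtype=float)
        if self.matrix.shape != (len(self.muscle_names), len(DOF_NAMES)):
            raise ValueError(f"synergy matrix must be {len(self.muscle_names)}x{len(DOF_NAMES)}")
        if np.any(self.matrix < 0) or np.any(self.tonic < 0):
            raise ValueError("synergy entries and tonic must be nonnegative")
        if np.any(self.matrix.sum(axis=0) == 0):
            raise ValueError("every DOF must drive at least one muscle")

    def to_json(self) -> str:
        return json.dumps(
            {"matrix": self.matrix.tolist(), "tonic": self.tonic.tolist(),
             "muscle_names": list(self.muscle_names)}
        )

    @classmethod
    def from_json(cls, text: str) -> "SynergyMatrix":
        d = json.loads(text)
        return cls(np.array(d["matrix"]), np.array(d["tonic"]), tuple(d["muscle_names"]))


def default_synergy() -> SynergyMatrix:
    """Qualitative anatomy: each DOF has a dominant muscle plus weak cross-talk.

    Deltoid middle/anterior/posterior parts dominate shoulder abduction,
    flexion and rotation; biceps dominates elbow flexion with triceps
    co-contracting as the antagonist stabiliser; trapezius supports
    abduction (scapular upward rotation); the forearm rotator channel
    ("long head" electrode) dominates forearm rotation.  Off-dominant
    entries are weak cross-talk, so every electrode carries a genuine
    primary signal.
    """
    #        abd   flex  rot   elbow forearm
    m = np.array(
        [
            [0.50, 0.10, 0.10, 0.00, 0.00],  # trapezius
            [0.00, 0.00, 0.00, 0.10, 0.85],  # long_head
            [0.00, 0.10, 0.00, 0.85, 0.10],  # biceps
            [0.00, 0.00, 0.10, 0.50, 0.05],  # triceps
            [0.10, 0.85, 0.10, 0.00, 0.00],  # deltoid_ant
            [0.85, 0.10, 0.05, 0.00, 0.00],  # deltoid_mid
            [0.05, 0.10, 0.85, 0.00, 0.00],  # deltoid_post
        ]
    )
    return SynergyMatrix(matrix=m, tonic=np.full(len(MUSCLE_NAMES), 0.02))


# reference drive-model gains: phasic velocity gain, position-holding gain,
# and the velocity normalisation (deg/s) that keeps envelopes inside [0, 1]
# for in-range minimum-jerk motions
ALPHA_PHASIC = 0.8
BETA_HOLD = 0.5
OMEGA_REF = 300.0


def activation_from_trajectory(
    traj: JointTrajectory,
    synergy: SynergyMatrix | None = None,
    alpha: float = ALPHA_PHASIC,
    beta: float = BETA_HOLD,
    omega_ref: float = OMEGA_REF,
    clip: bool = True,
) -> np.ndarray:
    """Per-muscle activation envelopes in [0, 1], shape (7, n_times).

    DOF drive combines a phasic term alpha * |dtheta/dt| / omega_ref and a
    holding term beta * |theta| / theta_ref (theta_ref = the DOF's largest
    planning-range magnitude), summed through the synergy matrix with the
    tonic baseline, clipped to [0, 1].
    """
    synergy = synergy or default_synergy()
    dt = 1.0 / traj.fs
    drives = np.empty_like(traj.angles)
    for i, dof in enumerate(traj.dof_names):
        lo, hi = DOF_RANGES[dof]
        theta_ref = max(abs(lo), abs(hi))
        vel = np.gradient(traj.angles[i], dt)
        drives[i] = alpha * np.abs(vel) / omega_ref + beta * np.abs(traj.angles[i]) / theta_ref
    env = synergy.matrix @ drives + synergy.tonic[:, None]
    return np.clip(env, 0.0, 1.0) if clip else env


@dataclass
class EmgNoiseModel:
    """Interference model for the synthetic sEMG carrier."""

    band: tuple[float, float] = (20.0, 150.0)
    mains_amp: float = 0.05
    mains_freq: float = 50.0
    drift_amp: float = 0.05
    drift_corner: float = 1.0
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError("carrier band must satisfy 0 < low < high")
        if min(self.mains_amp, self.drift_amp, self.noise_sd) < 0:
            raise ValueError("noise amplitudes must be nonnegative")


def gen_emg(
    envelopes: np.ndarray,
    fs: float,
    noise: EmgNoiseModel | None = None,
    channel_names: tuple[str, ...] | None = None,
) -> EmgRecording:
    """Amplitude-modulated synthetic sEMG: envelope x unit-RMS carrier + interference."""
    noise = noise or EmgNoiseModel()
    env = np.atleast_2d(np.asarray(envelopes, dtype=float))
    if np.any(env < 0) or np.any(env > 1):
        raise ValueError("envelopes must lie in [0, 1]")
    if noise.band[1] >= fs / 2:
        raise ValueError(f"carrier band {noise.band} incompatible with fs={fs} (Nyquist {fs / 2})")
    n_ch, n = env.shape
    rng = np.random.default_rng(noise.seed)
    sos = sps.butter(4, noise.band, btype="bandpass", fs=fs, output="sos")
    carrier = sps.sosfiltfilt(sos, rng.standard_normal((n_ch, n)), axis=1)
    carrier /= np.sqrt(np.mean(carrier**2, axis=1, keepdims=True))  # unit RMS
    t = np.arange(n) / fs
    x = env * carrier
    if noise.mains_amp > 0:
        phases = rng.uniform(0, 2 * np.pi, size=n_ch)
        x = x + noise.mains_amp * np.sin(2 * np.pi * noise.mains_freq * t[None, :] + phases[:, None])
    if noise.drift_amp > 0:
        sos_lp = sps.butter(2, noise.drift_corner, btype="lowpass", fs=fs, output="sos")
        drift = sps.sosfiltfilt(sos_lp, rng.standard_normal((n_ch, n)), axis=1)
        sd = drift.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        x = x + noise.drift_amp * drift / sd
    if noise.noise_sd > 0:
        x = x + noise.noise_sd * rng.standard_normal((n_ch, n))
    names = channel_names or (MUSCLE_NAMES if n_ch == len(MUSCLE_NAMES) else None)
    return EmgRecording(samples=x, fs=fs, channel_names=list(names) if names else None)


# ----------------------------------------------------------------------
# gesture windows
# ----------------------------------------------------------------------

# per-class channel emphasis on the 8 armband channels; palm_up/palm_down
# share emphasised channels, which is what makes them confusable
_GESTURE_TEMPLATES = {
    "clench": np.array([0.90, 0.80, 0.70, 0.60, 0.30, 0.20, 0.20, 0.30]),
    "relax": np.array([0.08, 0.08, 0.08, 0.08, 0.08, 0.08, 0.08, 0.08]),
    "palm_up": np.array([0.20, 0.30, 0.30, 0.20, 0.80, 0.90, 0.50, 0.30]),
    "palm_down": np.array([0.30, 0.20, 0.30, 0.20, 0.50, 0.80, 0.90, 0.40]),
}

GESTURE_FS = 200.0


def gesture_templates(overlap: float = 0.0) -> dict[str, np.ndarray]:
    """Class channel-emphasis templates; ``overlap`` in [0, 1] pulls the
    palm_up and palm_down templates linearly toward their mean (1 = identical)."""
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must lie in [0, 1]")
    t = {k: v.copy() for k, v in _GESTURE_TEMPLATES.items()}
    mean = 0.5 * (t["palm_up"] + t["palm_down"])
    t["palm_up"] = (1 - overlap) * t["palm_up"] + overlap * mean
    t["palm_down"] = (1 - overlap) * t["palm_down"] + overlap * mean
    return t


def gen_gesture_dataset(
    n_per_class: int,
    overlap: float = 0.0,
    seed: int = 0,
    amp_jitter: float = 0.15,
    sensor_noise_sd: float = 0.02,
) -> GestureDataset:
    """Balanced 4-class dataset of 8 x 200 windows.

    Each window is a class template (with per-window amplitude jitter)
    shaped by a smooth Tukey taper, modulating a band-limited Gaussian
    carrier, plus sensor noise.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    templates = gesture_templates(overlap)
    taper = sps.windows.tukey(WINDOW_SAMPLES, alpha=0.3)
    sos = sps.butter(4, (20.0, 95.0), btype="bandpass", fs=GESTURE_FS, output="sos")
    windows, labels = [], []
    for cls in CLASSES:
        base = templates[cls]
        for _ in range(n_per_class):
            gains = base * (1.0 + amp_jitter * rng.uniform(-1, 1, size=WINDOW_CHANNELS))
            gains *= 1.0 + 0.5 * amp_jitter * rng.uniform(-1, 1)  # window-level effort jitter
            carrier = sps.sosfiltfilt(sos, rng.standard_normal((WINDOW_CHANNELS, WINDOW_SAMPLES)), axis=1)
            carrier /= np.sqrt(np.mean(carrier**2, axis=1, keepdims=True))
            w = gains[:, None] * taper[None, :] * carrier
            w += sensor_noise_sd * rng.standard_normal(w.shape)
            windows.append(w)
            labels.append(cls)
    return GestureDataset(np.stack(windows), np.asarray(labels))


# ----------------------------------------------------------------------
# full arm dataset (EMG + trajectory + IMU streams)
# ----------------------------------------------------------------------


@dataclass
class ArmDataset:
    """Consistent triple produced by one simulated acquisition session."""

    emg: EmgRecording
    trajectory: JointTrajectory
    streams: dict[str, OrientationStream]
    protocol: ProtocolSpec
    motion_spec: list[tuple[str, float]]


def gen_arm_dataset(
    motion_spec: list[tuple[str, float]],
    synergy: SynergyMatrix | None = None,
    protocol: ProtocolSpec | None = None,
    noise: EmgNoiseModel | None = None,
    seed: int = 0,
    imu_fs: float = 100.0,
) -> ArmDataset:
    """Simulate one session: trajectory -> activations -> EMG, plus IMU streams.

    DOFs listed in ``motion_spec`` move simultaneously under the shared
    protocol timing; DOFs absent from the motion spec stay at exactly 0 deg (the
    inactive-DOF ground truth).  The IMU quaternions are composed with the
    same conventions the kinematics module decodes.
    """
    protocol = protocol or ProtocolSpec()
    synergy = synergy or default_synergy()
    noise = noise or EmgNoiseModel()
    dofs = [d for d, _ in motion_spec]
    if len(set(dofs)) != len(dofs):
        raise ValueError("duplicate DOFs in motion_spec")
    n = int(round(protocol.total_s * protocol.fs))
    angles = np.zeros((len(DOF_NAMES), n))
    for dof, target in motion_spec:
        single = gen_trajectory(dof, target, protocol)
        angles[DOF_NAMES.index(dof)] = single.angles[DOF_NAMES.index(dof)]
    times = np.arange(n) / protocol.fs
    traj = JointTrajectory(times=times, angles=angles)

    env = activation_from_trajectory(traj, synergy)
    noise_seeded = EmgNoiseModel(**{**asdict(noise), "seed": seed})
    emg = gen_emg(env, protocol.fs, noise_seeded)

    step = int(round(protocol.fs / imu_fs))
    if step < 1 or not np.isclose(step * imu_fs, protocol.fs):
        raise ValueError("imu_fs must divide the protocol sampling rate")
    idx = np.arange(0, n, step)
    abd, flex, rot, eflex, pron = angles[:, idx]
    q_sh = kinematics.compose_shoulder(abd, flex, rot)
    q_el_rel = kinematics.compose_elbow(eflex, pron)
    q_el = kinematics.quat_multiply(q_sh, q_el_rel)
    q_el /= np.linalg.norm(q_el, axis=1, keepdims=True)
    ident = np.tile([1.0, 0.0, 0.0, 0.0], (len(idx), 1))
    t_imu = times[idx]
    streams = {
        "base": OrientationStream(t_imu, ident, "base"),
        "shoulder": OrientationStream(t_imu, q_sh, "shoulder"),
        "elbow": OrientationStream(t_imu, q_el, "elbow"),
    }
    return ArmDataset(emg=emg, trajectory=traj, streams=streams, protocol=protocol,
                      motion_spec=list(motion_spec))
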