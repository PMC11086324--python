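"""IMU orientation streams to joint angles.

Three body-worn IMUs provide orientation quaternions: a Base unit on the
chest (static reference), a Shoulder unit on the upper arm and an Elbow
unit on the forearm.  Ground-truth joint angles are obtained by expressing
each sensor relative to the base, zeroing against a calibration pose, and
decomposing the relative rotation:

* shoulder (3 DOF): intrinsic Z-X-Y Euler sequence mapped to
  (flexion/extension, abduction/adduction, internal rotation); reported as
  (abd, flex, rot);
* elbow/forearm (2 DOF): flexion about the shared x-axis followed by
  pronation about the forearm long axis (y), recovered in closed form from
  the rotation matrix — this two-axis decomposition has no gimbal lock.

Quaternions follow the Hamilton convention and are stored (w, x, y, z);
frames are right-handed.  Angle traces are unwrapped across samples to
avoid +/-180 degree jumps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .trajectory import JointTrajectory

__all__ = [
    "OrientationStream",
    "quat_conjugate",
    "quat_multiply",
    "relative_orientation",
    "calibrate_zero",
    "compose_shoulder",
    "decompose_shoulder",
    "compose_elbow",
    "decompose_elbow",
    "angles_from_streams",
]

_UNIT_TOL = 1e-6


def _check_unit(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    norms = np.linalg.norm(q, axis=-1)
    if np.any(np.abs(norms - 1.0) > 1e-3):
        raise ValueError("quaternion norm deviates from 1 beyond tolerance")
    return q / norms[..., None]


def _to_rotation(q_wxyz: np.ndarray) -> Rotation:
    q = np.asarray(q_wxyz, dtype=float)
    return Rotation.from_quat(np.roll(q, -1, axis=-1))  # wxyz -> xyzw


def _from_rotation(r: Rotation) -> np.ndarray:
    q = r.as_quat()  # xyzw
    q = np.roll(q, 1, axis=-1)  # -> wxyz
    # canonicalise sign (w >= 0) so round trips are stable
    flip = q[..., 0] < 0
    q = np.where(flip[..., None], -q, q)
    return q


@dataclass
class OrientationStream:
    """Unit-quaternion orientation samples on a uniform time grid.

    ``quats`` has shape (n, 4) in (w, x, y, z) order; ``sensor_id`` is one
    of {base, shoulder, elbow}.
    """

    times: np.ndarray
    quats: np.ndarray
    sensor_id: str = "base"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.quats = np.asarray(self.quats, dtype=float)
        if self.quats.shape != (len(self.times), 4):
            raise ValueError("quats must be (n_times, 4)")
        norms = np.linalg.norm(self.quats, axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise ValueError("stream quaternions must be unit within 1e-6")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("stream requires a uniform time grid")

    def index_at(self, t: float) -> int:
        if t < self.times[0] - 1e-9 or t > self.times[-1] + 1e-9:
            raise ValueError(f"time {t} outside stream range [{self.times[0]}, {self.times[-1]}]")
        return int(np.argmin(np.abs(self.times - t)))


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product q1 (x) q2, both (w, x, y, z)."""
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    w1, x1, y1, z1 = np.moveaxis(q1, -1, 0)
    w2, x2, y2, z2 = np.moveaxis(q2, -1, 0)
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def relative_orientation(q_a: np.ndarray, q_b: np.ndarray) -> np.ndarray:
    """Rotation taking frame a to frame b: conj(q_a) (x) q_b (unit norm)."""
    q_a = _check_unit(q_a)
    q_b = _check_unit(q_b)
    out = quat_multiply(quat_conjugate(q_a), q_b)
    return out / np.linalg.norm(out, axis=-1, keepdims=True)


def calibrate_zero(stream: OrientationStream, base_stream: OrientationStream, t0: float) -> OrientationStream:
    """Re-express a sensor stream relative to the base sensor and the t0 pose.

    Each sample becomes conj(q_rel(t0)) (x) q_rel(t) with
    q_rel(t) = conj(q_base(t)) (x) q_sensor(t); the output at t0 is the
    identity quaternion.  A rigid rotation applied to both streams (a
    common world-frame change) leaves the result unchanged.
    """
    if len(stream.times) != len(base_stream.times) or not np.allclose(
        stream.times, base_stream.times
    ):
        raise ValueError("sensor and base streams must share the same time grid")
    i0 = stream.index_at(t0)
    q_rel = relative_orientation(base_stream.quats, stream.quats)
    q0_inv = quat_conjugate(q_rel[i0])
    out = quat_multiply(q0_inv[None, :], q_rel)
    out = out / np.linalg.norm(out, axis=1, keepdims=True)
    return OrientationStream(times=stream.times.copy(), quats=out, sensor_id=stream.sensor_id)


# ----------------------------------------------------------------------
# shoulder: 3 DOF, intrinsic Z-X-Y (z = flex, x = abd, y = rot)
# ----------------------------------------------------------------------

_GIMBAL_MARGIN_DEG = 1.0


def compose_shoulder(abd: float, flex: float, rot: float) -> np.ndarray:
    """Quaternion for shoulder angles (degrees): intrinsic Rz(flex) Rx(abd) Ry(rot)."""
    r = Rotation.from_euler("ZXY", np.stack([np.atleast_1d(flex), np.atleast_1d(abd), np.atleast_1d(rot)], axis=-1), degrees=True)
    q = _from_rotation(r)
    return q[0] if np.isscalar(abd) or np.ndim(abd) == 0 else q


def decompose_shoulder(q_rel: np.ndarray) -> tuple[float, float, float]:
    """(abd, flex, rot) in degrees from a relative shoulder quaternion.

    Warns when the middle (abduction) angle is within 1 degree of the
    +/-90 degree gimbal singularity, where flexion and rotation become
    poorly separated.
    """
    q = _check_unit(np.asarray(q_rel, dtype=float))
    single = q.ndim == 1
    r = _to_rotation(np.atleast_2d(q))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns at exact lock; we flag below
        flex, abd, rot = r.as_euler("ZXY", degrees=True).T
    if np.any(np.abs(np.abs(abd) - 90.0) < _GIMBAL_MARGIN_DEG):
        warnings.warn("shoulder decomposition within 1 degree of gimbal lock", stacklevel=2)
    if single:
        return float(abd[0]), float(flex[0]), float(rot[0])
    return abd, flex, rot


# ----------------------------------------------------------------------
# elbow: 2 DOF, R = Rx(flex) Ry(pronation) in closed form
# ----------------------------------------------------------------------


def compose_elbow(flex: float, pronation: float) -> np.ndarray:
    """Quaternion for elbow flexion then forearm pronation (degrees)."""
    r = Rotation.from_euler(
        "XY",
        np.stack([np.atleast_1d(flex), np.atleast_1d(pronation)], axis=-1),
        degrees=True,
    )
    q = _from_rotation(r)
    return q[0] if np.ndim(flex) == 0 else q


def decompose_elbow(q_rel: np.ndarray) -> tuple[float, float]:
    """(flexion, pronation) in degrees from a relative elbow quaternion.

    For R = Rx(a) Ry(b): b = atan2(R02, R00), a = atan2(R21, R11); both
    angles are uniquely determined (no singular configuration).
    """
    q = _check_unit(np.asarray(q_rel, dtype=float))
    single = q.ndim == 1
    m = _to_rotation(np.atleast_2d(q)).as_matrix()
    pron = np.degrees(np.arctan2(m[:, 0, 2], m[:, 0, 0]))
    flex = np.degrees(np.arctan2(m[:, 2, 1], m[:, 1, 1]))
    if single:
        return float(flex[0]), float(pron[0])
    return flex, pron


def angles_from_streams(
    base: OrientationStream,
    shoulder: OrientationStream,
    elbow: OrientationStream,
    t0: float | None = None,
    unwrap: bool = True,
) -> JointTrajectory:
    """Full pipeline: calibrate both sensors at t0, decompose, unwrap.

    The elbow sensor tracks the forearm in the world frame, so the elbow
    rotation is taken relative to the (calibrated) shoulder orientation.
    Returns a 5-DOF JointTrajectory (shoulder_abd, shoulder_flex,
    shoulder_rot, elbow_flex, forearm_rot).
    """
    if t0 is None:
        t0 = float(base.times[0])
    sh = calibrate_zero(shoulder, base, t0)
    el = calibrate_zero(elbow, base, t0)
    abd, flex, rot = decompose_shoulder(sh.quats)
    q_elbow_rel = quat_multiply(quat_conjugate(sh.quats), el.quats)
    q_elbow_rel /= np.linalg.norm(q_elbow_rel, axis=1, keepdims=True)
    eflex, pron = decompose_elbow(q_elbow_rel)
    angles = np.vstack([abd, flex, rot, eflex, pron])
    if unwrap:
        angles = np.degrees(np.unwrap(np.radians(angles), axis=1))
    return JointTrajectory(times=base.times.copy(), angles=angles)
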