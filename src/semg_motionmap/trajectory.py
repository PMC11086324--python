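"""Joint-angle trajectories for the five modelled arm degrees of freedom.

The arm model has three shoulder DOFs (abduction/adduction,
flexion/extension, internal/external rotation), elbow flexion/extension and
forearm rotation.  Motion-planning ranges in degrees:

====================  ===========
DOF                   range (deg)
====================  ===========
shoulder_abd          0 to 90
shoulder_flex         0 to 90
shoulder_rot          0 to 90
elbow_flex            0 to 120
forearm_rot           -30 to 150
====================  ===========
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DOF_NAMES", "DOF_RANGES", "JointTrajectory"]

DOF_NAMES = ("shoulder_abd", "shoulder_flex", "shoulder_rot", "elbow_flex", "forearm_rot")

DOF_RANGES: dict[str, tuple[float, float]] = {
    "shoulder_abd": (0.0, 90.0),
    "shoulder_flex": (0.0, 90.0),
    "shoulder_rot": (0.0, 90.0),
    "elbow_flex": (0.0, 120.0),
    "forearm_rot": (-30.0, 150.0),
}


@dataclass
class JointTrajectory:
    """Time-indexed joint angles in degrees on a uniform grid.

    ``angles`` has shape (n_dofs, n_times); rows follow ``dof_names``.
    """

    times: np.ndarray
    angles: np.ndarray
    dof_names: tuple[str, ...] = DOF_NAMES

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.angles = np.atleast_2d(np.asarray(self.angles, dtype=float))
        if self.angles.shape != (len(self.dof_names), len(self.times)):
            raise ValueError(
                f"angles shape {self.angles.shape} does not match "
                f"({len(self.dof_names)} dofs, {len(self.times)} times)"
            )
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("trajectory requires a uniform time grid")

    @property
    def fs(self) -> float:
        if len(self.times) < 2:
            raise ValueError("cannot infer rate from fewer than 2 samples")
        return 1.0 / (self.times[1] - self.times[0])

    def dof(self, name: str) -> np.ndarray:
        return self.angles[self.dof_names.index(name)]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.angles.T, columns=list(self.dof_names))
        df.insert(0, "time_s", self.times)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "JointTrajectory":
        df = pd.read_csv(path)
        return cls(
            times=df["time_s"].to_numpy(dtype=float),
            angles=df.drop(columns=["time_s"]).to_numpy(dtype=float).T,
            dof_names=tuple(c for c in df.columns if c != "time_s"),
        )
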