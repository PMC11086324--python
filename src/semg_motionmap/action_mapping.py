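"""Gesture and trajectory streams to robot-arm command logs.

Gesture semantics: a clench closes the claw, a relax opens it, palm-up is
the emergency stop (all joint commands suppressed), palm-down resumes from
the stop.  Joint-angle frames pass through as JOINT_SET commands only while
the controller is RUNNING.  The state machine is a pure function of
(state, event), so command logs are fully deterministic; per-window gesture
predictions are debounced (k identical consecutive labels) before they
become events.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .trajectory import DOF_NAMES, DOF_RANGES, JointTrajectory

__all__ = [
    "GESTURE_EVENTS",
    "ControllerState",
    "Command",
    "debounce",
    "step",
    "script_task",
    "commands_to_jsonl",
]

GESTURE_EVENTS = ("clench", "relax", "palm_up", "palm_down")


@dataclass(frozen=True)
class ControllerState:
    """mode in {RUNNING, ESTOP}; claw in {OPEN, CLOSED}."""

    mode: str = "RUNNING"
    claw: str = "OPEN"


@dataclass(frozen=True)
class Command:
    """kind in {CLAW_CLOSE, CLAW_OPEN, ESTOP, RESUME, JOINT_SET}."""

    kind: str
    timestamp: float = 0.0
    angles: tuple[float, ...] | None = None  # 5 joint angles for JOINT_SET

    def __post_init__(self) -> None:
        if self.kind == "JOINT_SET":
            if self.angles is None or len(self.angles) != len(DOF_NAMES):
                raise ValueError("JOINT_SET requires 5 joint angles")
            for dof, a in zip(DOF_NAMES, self.angles):
                lo, hi = DOF_RANGES[dof]
                if not lo - 5.0 <= a <= hi + 5.0:
                    raise ValueError(f"JOINT_SET angle {a} outside {dof} range [{lo}, {hi}]")

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "timestamp": self.timestamp}
        if self.angles is not None:
            d["angles"] = list(self.angles)
        return d


def debounce(labels, k: int = 3):
    """Collapse a per-window label stream into stable gesture events.

    An event fires when ``k`` consecutive identical labels arrive and the
    label differs from the previous event.  Returns a list of
    (index, label) pairs, the index being the position of the k-th
    confirming window.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    events: list[tuple[int, str]] = []
    run_label, run_len, last_event = None, 0, None
    for i, lab in enumerate(labels):
        if lab == run_label:
            run_len += 1
        else:
            run_label, run_len = lab, 1
        if run_len >= k and lab != last_event:
            events.append((i, lab))
            last_event = lab
    return events


def step(state: ControllerState, event, timestamp: float = 0.0):
    """One transition: returns (new_state, list of emitted commands).

    ``event`` is a gesture label or a joint-frame (sequence of 5 angles in
    degrees).  Unknown events are no-ops.  Claw commands are idempotent:
    a clench while the claw is already closed emits nothing.
    """
    cmds: list[Command] = []
    if isinstance(event, str):
        if event == "palm_up":
            if state.mode != "ESTOP":
                state = replace(state, mode="ESTOP")
                cmds.append(Command("ESTOP", timestamp))
        elif event == "palm_down":
            if state.mode == "ESTOP":  # resume only gated from the stop state
                state = replace(state, mode="RUNNING")
                cmds.append(Command("RESUME", timestamp))
        elif event == "clench":
            if state.mode == "RUNNING" and state.claw != "CLOSED":
                state = replace(state, claw="CLOSED")
                cmds.append(Command("CLAW_CLOSE", timestamp))
        elif event == "relax":
            if state.mode == "RUNNING" and state.claw != "OPEN":
                state = replace(state, claw="OPEN")
                cmds.append(Command("CLAW_OPEN", timestamp))
        # anything else: no-op
    else:
        angles = tuple(float(a) for a in np.asarray(event, dtype=float))
        if state.mode == "RUNNING":
            cmds.append(Command("JOINT_SET", timestamp, angles))
    return state, cmds


def script_task(
    traj: JointTrajectory,
    gesture_events: list[tuple[float, str]],
    state: ControllerState | None = None,
) -> list[Command]:
    """Replay a scripted task: merge a joint trajectory with timed gestures.

    ``gesture_events`` is a list of (time_s, label).  Joint frames and
    gesture events are processed in time order (gesture first on ties); an
    emergency stop suppresses all subsequent JOINT_SETs until a resume.
    """
    state = state or ControllerState()
    stream: list[tuple[float, int, object]] = [(t, 0, lab) for t, lab in gesture_events]
    stream += [(t, 1, traj.angles[:, i]) for i, t in enumerate(traj.times)]
    stream.sort(key=lambda item: (item[0], item[1]))
    log: list[Command] = []
    for t, _, event in stream:
        state, cmds = step(state, event, timestamp=float(t))
        log.extend(cmds)
    return log


def commands_to_jsonl(commands: list[Command], path) -> None:
    with open(path, "w") as fh:
        for c in commands:
            fh.write(json.dumps(c.to_dict()) + "\n")
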