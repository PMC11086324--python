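"""Reference end-to-end experiments on the synthetic benchmarks.

Two experiments mirror the study design:

* ``run_gesture_experiment`` — generate a balanced 4-class gesture window
  dataset, train the hybrid conv + handcrafted-feature classifier on a
  stratified 75/25 split, and report the held-out confusion matrix with
  per-class recognition rates.
* ``run_angle_experiment`` — generate single-DOF acquisition sessions (five
  amplitude groups per DOF), extract normalised muscle features, train one
  backprop angle network per DOF, then evaluate on a combined-motion
  session (simultaneous shoulder abduction, elbow flexion and forearm
  rotation): maximum absolute error on the active DOFs and maximum
  predicted magnitude on the DOFs that stayed still.

Both are deterministic under their seed and return plain-dict reports.
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import train_test_split

from .angle_regression import BPAngleRegressor, predict_trajectory
from .gesture_recognition import (
    GestureDataset,
    GestureNetConfig,
    HybridGestureClassifier,
    evaluate_confusion,
)
from scipy.ndimage import uniform_filter1d

from .signal_processing import (
    EmgRecording,
    FeatureSeries,
    IntervalScaler,
    apply_filter_chain,
    design_filter_chain,
    sliding_features,
)
from .synthetic_data import (
    ArmDataset,
    EmgNoiseModel,
    ProtocolSpec,
    SynergyMatrix,
    default_synergy,
    gen_arm_dataset,
    gen_gesture_dataset,
)
from .trajectory import DOF_NAMES, DOF_RANGES

__all__ = [
    "amplitude_groups",
    "emg_to_features",
    "build_regression_matrix",
    "run_gesture_experiment",
    "run_angle_experiment",
    "ABDUCTION_AND_RAISE",
]

# combined "abduction and raise" motion: shoulder abduction, elbow flexion
# and forearm rotation move together; shoulder flexion and rotation stay still
ABDUCTION_AND_RAISE = [("shoulder_abd", 72.0), ("elbow_flex", 96.0), ("forearm_rot", 78.0)]

# feature-extraction defaults for the regression pipeline: a 300 ms RMS
# window stepped by 50 ms, then a 9-frame moving average — long enough to
# tame the stochastic carrier, short against the 1 s joint transitions
FEATURE_WINDOW_MS = 300.0
FEATURE_STEP_MS = 50.0
FEATURE_SMOOTH_FRAMES = 9


def amplitude_groups(dof: str, n_groups: int = 5) -> np.ndarray:
    """The planned per-DOF target amplitudes: five equal divisions of the range."""
    lo, hi = DOF_RANGES[dof]
    return lo + (hi - lo) * np.arange(1, n_groups + 1) / n_groups


def emg_to_features(
    rec: EmgRecording,
    window_ms: float = FEATURE_WINDOW_MS,
    step_ms: float = FEATURE_STEP_MS,
    smooth_frames: int = FEATURE_SMOOTH_FRAMES,
) -> FeatureSeries:
    """Filter chain -> sliding RMS -> moving-average smoothing."""
    chain = design_filter_chain(rec.fs)
    filtered = apply_filter_chain(rec, chain)
    feats = sliding_features(filtered, window_ms, step_ms, kind="RMS")
    if smooth_frames > 1 and feats.n_frames >= smooth_frames:
        # centred boxcar: no group delay, so smoothed features stay aligned
        # with the angle truth interpolated at the frame centres
        feats.frames = uniform_filter1d(feats.frames, smooth_frames, axis=1, mode="nearest")
    return feats


def build_regression_matrix(
    dataset: ArmDataset, feats: FeatureSeries, scaler: IntervalScaler
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(X, Y, frame_times): X = 7 scaled muscle features + normalised rep time,
    Y = the 5-DOF target angles interpolated at the frame centres."""
    scaled = scaler.transform(feats.frames)
    t_norm = dataset.protocol.normalized_rep_time(feats.frame_times)
    X = np.column_stack([scaled.T, t_norm])
    Y = np.stack(
        [
            np.interp(feats.frame_times, dataset.trajectory.times, dataset.trajectory.angles[i])
            for i in range(len(DOF_NAMES))
        ]
    )
    return X, Y, feats.frame_times


def run_gesture_experiment(
    n_per_class: int = 200,
    overlap: float = 0.3,
    seed: int = 11,
    test_fraction: float = 0.25,
    config: GestureNetConfig | None = None,
) -> dict:
    """Gesture benchmark: generate, split, train, evaluate held-out windows."""
    data = gen_gesture_dataset(n_per_class=n_per_class, overlap=overlap, seed=seed)
    idx_train, idx_test = train_test_split(
        np.arange(len(data)),
        test_size=test_fraction,
        random_state=seed % (2**32),
        stratify=data.labels,
    )
    train = GestureDataset(data.windows[idx_train], data.labels[idx_train])
    test = GestureDataset(data.windows[idx_test], data.labels[idx_test])
    cfg = config if config is not None else GestureNetConfig(seed=seed)
    model = HybridGestureClassifier(cfg).fit(train.windows, train.labels)
    cm = evaluate_confusion(model, test)
    return {
        "n_train": len(train),
        "n_test": len(test),
        "overlap": overlap,
        "seed": seed,
        "confusion_matrix": cm.to_dict(),
        "accuracy": cm.accuracy,
        "per_class_rates": cm.per_class_rates,
        "final_train_loss": model.history_["loss"][-1],
        "final_train_accuracy": model.history_["accuracy"][-1],
        "model": model,
    }


def _session_seed(seed: int, tag: int) -> int:
    return int((seed * 1000003 + tag) % (2**31 - 1))


def run_angle_experiment(
    seed: int = 11,
    motion_spec: list[tuple[str, float]] | None = None,
    synergy: SynergyMatrix | None = None,
    protocol: ProtocolSpec | None = None,
    noise: EmgNoiseModel | None = None,
    hidden: int = 20,
    mc: float = 0.9,
    eta0: float = 0.05,
    epochs: int = 600,
    batch_size: int | None = 64,
    weight_decay: float = 3e-4,
    train_frame_stride: int = 2,
    output_smooth_frames: int = 21,
    zero_target_weight: float = 2.0,
) -> dict:
    """Joint-angle benchmark: train per-DOF networks on single-DOF sessions,
    evaluate on the combined-motion session.

    Each DOF's network is trained on the features of *all* single-DOF
    sessions (its own five amplitude groups plus every other DOF's
    sessions, where its target angle is 0), so inactive-DOF suppression is
    learnable.  Returns per-DOF max/mean absolute errors on active DOFs and
    max predicted magnitude on the still DOFs.
    """
    motion_spec = motion_spec if motion_spec is not None else list(ABDUCTION_AND_RAISE)
    synergy = synergy or default_synergy()
    protocol = protocol or ProtocolSpec()
    noise = noise or EmgNoiseModel()

    # --- training sessions: five amplitude groups per DOF -------------
    sessions: list[ArmDataset] = []
    tag = 0
    for dof in DOF_NAMES:
        for target in amplitude_groups(dof):
            tag += 1
            sessions.append(
                gen_arm_dataset(
                    [(dof, float(target))],
                    synergy=synergy,
                    protocol=protocol,
                    noise=noise,
                    seed=_session_seed(seed, tag),
                )
            )
    session_feats = [emg_to_features(s.emg) for s in sessions]
    scaler = IntervalScaler().fit(np.concatenate([f.frames for f in session_feats], axis=1))
    Xs, Ys = [], []
    for sess, feats in zip(sessions, session_feats):
        X, Y, _ = build_regression_matrix(sess, feats, scaler)
        Xs.append(X)
        Ys.append(Y)
    # every-other-frame subsampling keeps the epoch cost down without
    # losing coverage (adjacent 50 ms frames are strongly correlated)
    X_train = np.concatenate(Xs, axis=0)[::train_frame_stride]
    Y_train = np.concatenate(Ys, axis=1)[:, ::train_frame_stride]

    # --- per-DOF networks ---------------------------------------------
    models: dict[str, BPAngleRegressor] = {}
    for i, dof in enumerate(DOF_NAMES):
        reg = BPAngleRegressor(
            hidden=hidden,
            mc=mc,
            eta0=eta0,
            epochs=epochs,
            batch_size=batch_size,
            weight_decay=weight_decay,
            angle_range=DOF_RANGES[dof],
            seed=_session_seed(seed, 9000 + i),
        )
        # zero-target frames are upweighted: accurate suppression while other
        # joints move is as important as tracking the DOF's own motion
        w = np.where(Y_train[i] == 0.0, zero_target_weight, 1.0)
        reg.fit(X_train, Y_train[i], sample_weight=w)
        models[dof] = reg

    # --- combined-motion test session ---------------------------------
    test_session = gen_arm_dataset(
        motion_spec, synergy=synergy, protocol=protocol, noise=noise,
        seed=_session_seed(seed, 555555),
    )
    test_feats = emg_to_features(test_session.emg)
    X_test, Y_test, frame_times = build_regression_matrix(test_session, test_feats, scaler)
    pred = predict_trajectory(
        models,
        FeatureSeries(
            scaler.transform(test_feats.frames), test_feats.frame_times,
            test_feats.feature_kind, test_feats.window_ms, test_feats.step_ms,
        ),
        time_channel=test_session.protocol.normalized_rep_time(frame_times),
    )
    if output_smooth_frames > 1:
        # centred smoothing of the predicted traces: joint angles are slow
        # against the 50 ms frame rate, so this removes frame-level jitter
        # with negligible lag bias
        pred.angles = uniform_filter1d(pred.angles, output_smooth_frames, axis=1, mode="nearest")

    active = [d for d, _ in motion_spec]
    inactive = [d for d in DOF_NAMES if d not in active]
    per_dof: dict[str, dict] = {}
    for i, dof in enumerate(DOF_NAMES):
        err = pred.angles[i] - Y_test[i]
        per_dof[dof] = {
            "active": dof in active,
            "max_abs_error": float(np.max(np.abs(err))),
            "mean_abs_error": float(np.mean(np.abs(err))),
            "max_abs_predicted": float(np.max(np.abs(pred.angles[i]))),
        }
    return {
        "seed": seed,
        "motion_spec": [(d, float(t)) for d, t in motion_spec],
        "n_train_frames": len(X_train),
        "n_test_frames": len(X_test),
        "per_dof": per_dof,
        "max_abs_error_active": max(per_dof[d]["max_abs_error"] for d in active),
        "max_abs_pred_inactive": max(per_dof[d]["max_abs_predicted"] for d in inactive),
        "models": models,
        "predicted": pred,
        "truth": Y_test,
        "frame_times": frame_times,
    }
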