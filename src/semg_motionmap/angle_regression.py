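"""From-scratch backpropagation regression of joint angles from muscle features.

A three-layer feedforward network (8 inputs -> H sigmoid hidden units ->
1 linear output) maps seven normalised per-muscle amplitude features plus
normalised motion time to one joint angle; one network is trained per degree
of freedom.  Training is classic full-batch backpropagation augmented with

* a momentum term
      dW(k+1) = (1 - mc) * eta * g + mc * dW(k)
  (same rule for the thresholds b), where g is the descent direction
  -dE/dW, mc the momentum factor, and
* a multiplicative adaptive learning-rate schedule on the epoch SSE
      eta <- 1.05 * eta   if SSE(k+1) <  SSE(k)
      eta <- 0.70 * eta   if SSE(k+1) >  1.04 * SSE(k)
      eta unchanged       otherwise.

Targets are min-max scaled to [0, 1] over the DOF's motion range before
training and mapped back to degrees at prediction time.  The error function
is E = 1/2 * sum_i w_i * (y_i - yhat_i)^2 with optional per-sample weights
w_i (default 1); the reported per-epoch SSE is sum_i (y_i - yhat_i)^2 in
scaled units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .signal_processing import FeatureSeries
from .trajectory import DOF_NAMES, DOF_RANGES, JointTrajectory

__all__ = [
    "TrainState",
    "BPAngleRegressor",
    "init_bp",
    "bp_forward",
    "momentum_step",
    "adapt_learning_rate",
    "weighted_mse",
    "train_bp",
    "predict_trajectory",
]

N_INPUTS = 8  # 7 muscle features + normalised motion time


@dataclass
class TrainState:
    """Mutable training bookkeeping: iteration, learning rate, momentum memory."""

    k: int = 0
    eta: float = 0.01
    mc: float = 0.9
    prev_deltas: dict = field(default_factory=dict)
    sse_history: list[float] = field(default_factory=list)
    eta_history: list[float] = field(default_factory=list)


def momentum_step(grad_term: np.ndarray, prev_delta: np.ndarray, eta: float, mc: float):
    """One momentum update increment.

    ``grad_term`` is the descent direction (the delta-rule term delta_i*p_j
    for weights, delta_i for thresholds); the new increment is
    (1 - mc) * eta * grad_term + mc * prev_delta.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    if not 0.0 <= mc <= 1.0:
        raise ValueError("mc must lie in [0, 1]")
    return (1.0 - mc) * eta * np.asarray(grad_term) + mc * np.asarray(prev_delta)


def adapt_learning_rate(eta: float, sse_new: float, sse_old: float) -> float:
    """Three-branch multiplicative learning-rate schedule (see module docs)."""
    if sse_new < 0 or sse_old < 0:
        raise ValueError("SSE values must be nonnegative")
    if sse_new < sse_old:
        return 1.05 * eta
    if sse_new > 1.04 * sse_old:
        return 0.7 * eta
    return eta


def weighted_mse(Y, Yhat, w=None) -> float:
    """(1/n) * sum_i w_i * (Y_i - Yhat_i)^2 with w_i defaulting to 1."""
    Y = np.asarray(Y, dtype=float)
    Yhat = np.asarray(Yhat, dtype=float)
    if Y.shape != Yhat.shape:
        raise ValueError("Y and Yhat must have equal length")
    if Y.size == 0:
        raise ValueError("need at least one sample")
    if w is None:
        w = np.ones_like(Y)
    else:
        w = np.broadcast_to(np.asarray(w, dtype=float), Y.shape)
    return float(np.mean(w * (Y - Yhat) ** 2))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class BPAngleRegressor(BaseEstimator, RegressorMixin):
    """Three-layer backprop network with momentum and adaptive learning rate.

    Parameters
    ----------
    hidden : int
        Hidden-node count H (default 20).
    mc : float
        Momentum factor in [0, 1] (default 0.9).
    eta0 : float
        Initial learning rate (default 0.01).
    epochs : int
        Training passes over the data (default 800).
    batch_size : int or None
        None (default) updates once per epoch on the full gradient; an
        integer switches to shuffled mini-batch updates (momentum memory
        carried across batches), which converges much faster on large
        heterogeneous training sets.  The learning-rate schedule always
        acts per epoch on the full-pass SSE.
    adapt_lr : bool
        Apply the multiplicative SSE schedule between epochs (default True).
    weight_decay : float
        Optional L2 penalty coefficient on the weight matrices (thresholds
        excluded).  0 gives the plain momentum/adaptive-rate algorithm.
        Single-session training data can underdetermine the muscle-to-angle
        decode; a small penalty biases the fit away from redundant
        cross-channel weights that do not generalise to combined motions.
    angle_range : (lo, hi) or None
        Output scaling range in degrees; inferred from the targets when None.
    seed : int
        Seed for the uniform [-0.5, 0.5] weight initialisation.

    Fitted attributes: ``W1_`` (8 x H), ``b1_`` (H), ``W2_`` (H x 1),
    ``b2_`` (1), ``train_state_`` with SSE and learning-rate histories.
    """

    def __init__(
        self,
        hidden: int = 20,
        mc: float = 0.9,
        eta0: float = 0.01,
        epochs: int = 800,
        batch_size: int | None = None,
        adapt_lr: bool = True,
        weight_decay: float = 0.0,
        angle_range: tuple[float, float] | None = None,
        seed: int = 0,
    ):
        self.hidden = hidden
        self.mc = mc
        self.eta0 = eta0
        self.epochs = epochs
        self.batch_size = batch_size
        self.adapt_lr = adapt_lr
        self.weight_decay = weight_decay
        self.angle_range = angle_range
        self.seed = seed

    # -- initialisation -------------------------------------------------

    def _init_params(self) -> None:
        if self.hidden < 1:
            raise ValueError("hidden must be >= 1")
        rng = np.random.default_rng(self.seed)
        self.W1_ = rng.uniform(-0.5, 0.5, size=(N_INPUTS, self.hidden))
        self.b1_ = np.zeros(self.hidden)
        self.W2_ = rng.uniform(-0.5, 0.5, size=(self.hidden, 1))
        self.b2_ = np.zeros(1)

    # -- scaling --------------------------------------------------------

    def _scale_y(self, y: np.ndarray) -> np.ndarray:
        lo, hi = self.angle_range_
        return (y - lo) / (hi - lo)

    def _unscale_y(self, ys: np.ndarray) -> np.ndarray:
        lo, hi = self.angle_range_
        return ys * (hi - lo) + lo

    # -- forward / gradients -------------------------------------------

    def _forward_scaled(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a = _sigmoid(X @ self.W1_ + self.b1_)
        return (a @ self.W2_ + self.b2_).ravel(), a

    def _gradients(self, X: np.ndarray, y_scaled: np.ndarray, w: np.ndarray) -> dict:
        """Descent directions -dE/dtheta for E = 1/(2n) sum w (y - yhat)^2.

        The per-sample mean keeps the learning-rate scale independent of
        the training-set size.
        """
        yhat, a = self._forward_scaled(X)
        err = w * (y_scaled - yhat) / len(y_scaled)  # n
        g_W2 = a.T @ err[:, None]
        g_b2 = np.array([err.sum()])
        delta_h = (err[:, None] @ self.W2_.T) * a * (1.0 - a)  # n x H
        g_W1 = X.T @ delta_h
        g_b1 = delta_h.sum(axis=0)
        if self.weight_decay:
            g_W1 = g_W1 - self.weight_decay * self.W1_
            g_W2 = g_W2 - self.weight_decay * self.W2_
        return {"W1": g_W1, "b1": g_b1, "W2": g_W2, "b2": g_b2, "_yhat": yhat}

    # -- sklearn API ----------------------------------------------------

    def fit(self, X, y, sample_weight=None) -> "BPAngleRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[1] != N_INPUTS:
            raise ValueError(f"X must be (n, {N_INPUTS}); got {X.shape}")
        if len(y) != len(X) or len(y) < 1:
            raise ValueError("need >= 1 sample with matching X/y lengths")
        w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, dtype=float)
        self.angle_range_ = (
            (float(y.min()), float(y.max())) if self.angle_range is None else tuple(self.angle_range)
        )
        if self.angle_range_[1] <= self.angle_range_[0]:
            raise ValueError("angle_range must have hi > lo")

        self._init_params()
        ys = self._scale_y(y)
        state = TrainState(
            eta=self.eta0,
            mc=self.mc,
            prev_deltas={key: 0.0 for key in ("W1", "b1", "W2", "b2")},
        )
        rng = np.random.default_rng(self.seed + 1)
        sse_prev = None
        sse0 = None
        for _epoch in range(self.epochs):
            if self.batch_size is None:
                grads = self._gradients(X, ys, w)
                sse = float(np.sum((ys - grads["_yhat"]) ** 2))
                batches = [grads]
            else:
                order = rng.permutation(len(ys))
                sse = 0.0
                batches = []
                for start in range(0, len(ys), self.batch_size):
                    idx = order[start : start + self.batch_size]
                    batches.append(("idx", idx))
                # full-pass SSE before this epoch's updates (schedule input)
                yhat, _ = self._forward_scaled(X)
                sse = float(np.sum((ys - yhat) ** 2))
            if sse0 is None:
                sse0 = max(sse, np.finfo(float).tiny)
            if sse > 1e6 * sse0:
                raise RuntimeError(
                    f"divergence: epoch {state.k} SSE {sse:.3g} exceeds 1e6 x initial {sse0:.3g}"
                )
            if sse_prev is not None and self.adapt_lr:
                state.eta = adapt_learning_rate(state.eta, sse, sse_prev)
            sse_prev = sse
            state.sse_history.append(sse)
            state.eta_history.append(state.eta)
            for entry in batches:
                if isinstance(entry, dict):
                    grads = entry
                else:
                    idx = entry[1]
                    grads = self._gradients(X[idx], ys[idx], w[idx])
                for key, param in (
                    ("W1", self.W1_),
                    ("b1", self.b1_),
                    ("W2", self.W2_),
                    ("b2", self.b2_),
                ):
                    delta = momentum_step(grads[key], state.prev_deltas[key], state.eta, state.mc)
                    param += delta
                    state.prev_deltas[key] = delta
            state.k += 1
        self.train_state_ = state
        self.n_features_in_ = N_INPUTS
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[1] != N_INPUTS:
            raise ValueError(f"X must have {N_INPUTS} features; got {X.shape[1]}")
        if not np.all(np.isfinite(X)):
            raise ValueError("inputs must be finite")
        if not hasattr(self, "W1_"):
            raise ValueError("regressor is not fitted")
        yhat = self._unscale_y(self._forward_scaled(X)[0])
        return yhat[0] if single else yhat


# ----------------------------------------------------------------------
# functional wrappers
# ----------------------------------------------------------------------


def init_bp(seed: int, H: int = 20, angle_range: tuple[float, float] = (0.0, 1.0)) -> BPAngleRegressor:
    """Create an initialised (untrained) 8 -> H -> 1 network.

    Weights are uniform in [-0.5, 0.5] from the seeded generator;
    thresholds start at zero.
    """
    net = BPAngleRegressor(hidden=H, seed=seed, angle_range=angle_range)
    net._init_params()
    net.angle_range_ = tuple(angle_range)
    return net


def bp_forward(net: BPAngleRegressor, x: np.ndarray):
    """Forward pass of one 8-vector (or batch) through the network, in degrees."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    x2 = np.atleast_2d(x)
    if x2.shape[1] != N_INPUTS:
        raise ValueError(f"input must have {N_INPUTS} entries")
    out = net._unscale_y(net._forward_scaled(x2)[0])
    return float(out[0]) if single else out


def train_bp(
    net: BPAngleRegressor,
    X: np.ndarray,
    y: np.ndarray,
    mc: float = 0.9,
    eta0: float = 0.01,
    epochs: int = 800,
    seed: int | None = None,
    sample_weight=None,
    adapt_lr: bool = True,
) -> tuple[BPAngleRegressor, TrainState]:
    """Train a (possibly fresh) network; returns (net, train state)."""
    net.set_params(mc=mc, eta0=eta0, epochs=epochs, adapt_lr=adapt_lr)
    if seed is not None:
        net.set_params(seed=seed)
    net.fit(X, y, sample_weight=sample_weight)
    return net, net.train_state_


def predict_trajectory(
    models: dict[str, BPAngleRegressor],
    features: FeatureSeries,
    time_channel: np.ndarray,
    clamp_margin: float = 5.0,
) -> JointTrajectory:
    """Predict all five DOF angle traces from a normalised feature stream.

    ``features`` holds the 7 per-muscle normalised frames; ``time_channel``
    is the normalised within-repetition motion time aligned to the frames.
    Predictions are clamped to each DOF's planning range widened by
    ``clamp_margin`` degrees.
    """
    missing = [d for d in DOF_NAMES if d not in models]
    if missing:
        raise ValueError(f"missing trained model(s) for DOF(s): {missing}")
    t = np.asarray(time_channel, dtype=float)
    if features.n_frames != len(t):
        raise ValueError("time channel length must match the number of feature frames")
    X = np.column_stack([features.frames.T, t])
    angles = np.empty((len(DOF_NAMES), len(t)))
    for i, dof in enumerate(DOF_NAMES):
        lo, hi = DOF_RANGES[dof]
        angles[i] = np.clip(models[dof].predict(X), lo - clamp_margin, hi + clamp_margin)
    return JointTrajectory(times=features.frame_times, angles=angles)
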