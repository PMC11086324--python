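"""Hybrid gesture classifier for 8-channel armband windows.

The classifier fuses two feature routes computed from an 8 x 200
(channel x time) sEMG window:

* a convolutional route — three convolutions and two max-poolings applied
  only along the time axis, so channels never mix (each electrode sits over
  a different muscle); the terminal maps have shape (128, 5, 8) and flatten
  to a 5120-vector;
* a handcrafted route — per-channel RMS amplitude plus mean and median
  frequency of the magnitude spectrum (3 features x 8 channels = 24).

The concatenated 5144-vector feeds two fully connected layers that produce
score vectors over the four gestures (clench, relax, palm_up, palm_down).
Training minimises softmax cross-entropy with mini-batch SGD; all layers are
implemented directly in numpy with explicit backpropagation, which keeps the
whole stack dependency-light and bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "CLASSES",
    "GestureWindow",
    "GestureDataset",
    "GestureNetConfig",
    "ConfusionMatrix",
    "HybridGestureClassifier",
    "conv_feature_extract",
    "handcrafted_features",
    "fuse_features",
    "train_gesture",
    "predict_gesture",
    "evaluate_confusion",
]

CLASSES = ("clench", "relax", "palm_up", "palm_down")
_CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}

WINDOW_CHANNELS = 8
WINDOW_SAMPLES = 200


@dataclass
class GestureWindow:
    """One labelled 8 x 200 armband window (normalised signal units)."""

    values: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (WINDOW_CHANNELS, WINDOW_SAMPLES):
            raise ValueError(
                f"gesture window must be {WINDOW_CHANNELS}x{WINDOW_SAMPLES}, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("gesture window contains non-finite values")
        if self.label is not None and self.label not in _CLASS_INDEX:
            raise ValueError(f"unknown gesture label {self.label!r}")


@dataclass
class GestureDataset:
    """Stack of gesture windows with string labels."""

    windows: np.ndarray  # (n, 8, 200)
    labels: np.ndarray  # (n,) of str

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.windows.ndim != 3 or self.windows.shape[1:] != (WINDOW_CHANNELS, WINDOW_SAMPLES):
            raise ValueError(f"windows must be (n, 8, 200), got {self.windows.shape}")
        if len(self.labels) != len(self.windows):
            raise ValueError("labels/windows length mismatch")

    def __len__(self) -> int:
        return len(self.windows)

    def save(self, directory) -> Path:
        """Write one CSV per window plus a ``manifest.csv`` (path,label)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, (w, lab) in enumerate(zip(self.windows, self.labels)):
            name = f"window_{i:05d}.csv"
            pd.DataFrame(w.T, columns=[f"ch{c + 1}" for c in range(WINDOW_CHANNELS)]).to_csv(
                directory / name, index=False
            )
            rows.append({"path": name, "label": lab})
        manifest = directory / "manifest.csv"
        pd.DataFrame(rows).to_csv(manifest, index=False)
        return manifest

    @classmethod
    def load(cls, manifest_path) -> "GestureDataset":
        manifest_path = Path(manifest_path)
        man = pd.read_csv(manifest_path)
        windows, labels = [], []
        for _, row in man.iterrows():
            df = pd.read_csv(manifest_path.parent / row["path"])
            windows.append(df.to_numpy(dtype=float).T)
            labels.append(row["label"])
        return cls(np.stack(windows), np.asarray(labels))


@dataclass
class GestureNetConfig:
    """Architecture and training hyper-parameters.

    The default conv/pool arithmetic maps 200 time samples to length 5:
    200 -conv13-> 188 -pool4-> 47 -conv8-> 40 -pool4-> 10 -conv6-> 5,
    with map counts 32/64/128, so the terminal maps are (128, 5, 8) and
    flatten to 5120 per window.
    """

    conv_maps: tuple[int, ...] = (32, 64, 128)
    conv_kernels: tuple[int, ...] = (13, 8, 6)
    pool_sizes: tuple[int, ...] = (4, 4)  # after conv1 and conv2
    fc_width: int = 128
    n_classes: int = 4
    learning_rate: float = 0.00681292
    dropout_rate: float = 0.5
    batch_size: int = 128
    epochs: int = 40
    seed: int = 0
    fs: float = 200.0  # armband sampling rate, for the frequency features

    def conv_output_shape(self) -> tuple[int, int, int]:
        """(maps, length, channels) of the terminal feature maps."""
        length = WINDOW_SAMPLES
        for i, k in enumerate(self.conv_kernels):
            length = length - k + 1
            if i < len(self.pool_sizes):
                length //= self.pool_sizes[i]
        return (self.conv_maps[-1], length, WINDOW_CHANNELS)

    def flat_dim(self) -> int:
        m, l, c = self.conv_output_shape()
        return m * l * c


@dataclass
class ConfusionMatrix:
    """4 x 4 count matrix, rows = true class, columns = predicted."""

    counts: np.ndarray
    class_order: tuple[str, ...] = CLASSES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError(f"confusion matrix must be {k}x{k}")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be nonnegative")

    @property
    def accuracy(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else float("nan")

    @property
    def per_class_rates(self) -> dict[str, float]:
        rates = {}
        for i, c in enumerate(self.class_order):
            row = self.counts[i].sum()
            rates[c] = float(self.counts[i, i] / row) if row else float("nan")
        return rates

    def to_dict(self) -> dict:
        return {
            "class_order": list(self.class_order),
            "counts": self.counts.tolist(),
            "accuracy": self.accuracy,
            "per_class_rates": self.per_class_rates,
        }


# ----------------------------------------------------------------------
# numpy layers (time-only convolution, max pooling, dense, dropout)
# ----------------------------------------------------------------------


class _ConvTime:
    """Convolution along the time axis only; kernels span 1 channel.

    Input/output layout: (batch, maps, length, channels).  Implemented as
    im2col + matmul so the heavy lifting runs in BLAS.
    """

    def __init__(self, in_maps: int, out_maps: int, kernel: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_maps * kernel))  # He init for ReLU stacks
        self.W = (rng.standard_normal((out_maps, in_maps, kernel)) * scale).astype(np.float32)
        self.b = np.zeros(out_maps, dtype=np.float32)
        self.kernel = kernel

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k = self.kernel
        B, cin, L, C = x.shape
        lout = L - k + 1
        win = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)  # (B,cin,lout,C,k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4)).reshape(B * lout * C, cin * k)
        wmat = self.W.reshape(self.W.shape[0], cin * k)
        out = cols @ wmat.T + self.b
        if train:
            self._cols, self._xshape = cols, x.shape
        return out.reshape(B, lout, C, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, cin, L, C = self._xshape
        out_maps, _, k = self.W.shape
        lout = L - k + 1
        d2 = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(B * lout * C, out_maps)
        self.dW = (d2.T @ self._cols).reshape(self.W.shape)
        self.db = d2.sum(axis=0)
        dcols = (d2 @ self.W.reshape(out_maps, cin * k)).reshape(B, lout, C, cin, k)
        dx = np.zeros((B, cin, L, C), dtype=np.float32)
        for j in range(k):  # col2im scatter-add, k is small
            dx[:, :, j : j + lout, :] += dcols[..., j].transpose(0, 3, 1, 2)
        self._cols = None
        return dx

    def params(self):
        return [("W", self), ("b", self)]


class _MaxPoolTime:
    """Non-overlapping max pooling along the time axis."""

    def __init__(self, pool: int):
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        p = self.pool
        B, M, L, C = x.shape
        lt = (L // p) * p
        xr = x[:, :, :lt, :].reshape(B, M, lt // p, p, C)
        out = xr.max(axis=3)
        if train:
            self._argmax, self._xshape, self._lt = xr.argmax(axis=3), x.shape, lt
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        p = self.pool
        B, M, L, C = self._xshape
        dxr = np.zeros((B, M, self._lt // p, p, C), dtype=np.float32)
        np.put_along_axis(dxr, self._argmax[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dx = np.zeros((B, M, L, C), dtype=np.float32)
        dx[:, :, : self._lt, :] = dxr.reshape(B, M, self._lt, C)
        return dx


class _ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx


class _Dropout:
    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None = None):
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ----------------------------------------------------------------------
# handcrafted route
# ----------------------------------------------------------------------


def handcrafted_features(window: np.ndarray | GestureWindow, fs: float = 200.0) -> np.ndarray:
    """Per-channel [RMS, mean frequency, median frequency] -> 24-vector.

    Frequencies come from the magnitude spectrum of the window (DC
    excluded): mean frequency is the spectral centroid, median frequency
    splits the spectral power in half.  An all-zero channel yields zero
    for all three features (degenerate-spectrum rule).
    """
    w = window.values if isinstance(window, GestureWindow) else np.asarray(window, dtype=float)
    if w.ndim != 2:
        raise ValueError("window must be 2-D (channels x time)")
    n = w.shape[1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)[1:]  # exclude DC
    feats = np.empty(w.shape[0] * 3)
    for c in range(w.shape[0]):
        x = w[c]
        r = float(np.sqrt(np.mean(x**2)))
        if r == 0.0:
            feats[3 * c : 3 * c + 3] = 0.0
            continue
        power = np.abs(np.fft.rfft(x))[1:] ** 2
        total = power.sum()
        if total == 0.0:
            mnf = mdf = 0.0
        else:
            mnf = float(np.sum(freqs * power) / total)
            mdf = float(freqs[np.searchsorted(np.cumsum(power), total / 2.0)])
        feats[3 * c : 3 * c + 3] = (r, mnf, mdf)
    return feats


def fuse_features(cnn_vec: np.ndarray, hand_vec: np.ndarray) -> np.ndarray:
    """Concatenate the convolutional and handcrafted feature vectors (cnn first)."""
    cnn_vec = np.asarray(cnn_vec, dtype=float).ravel()
    hand_vec = np.asarray(hand_vec, dtype=float).ravel()
    if not (np.all(np.isfinite(cnn_vec)) and np.all(np.isfinite(hand_vec))):
        raise ValueError("feature vectors must be finite")
    return np.concatenate([cnn_vec, hand_vec])


# ----------------------------------------------------------------------
# estimator
# ----------------------------------------------------------------------


class HybridGestureClassifier(BaseEstimator, ClassifierMixin):
    """Multi-feature-fusion conv net over 8 x 200 sEMG windows.

    sklearn-style estimator: ``fit(X, y)`` with ``X`` of shape
    (n, 8, 200) and string or integer labels, ``predict`` /
    ``predict_proba`` for inference.  All parameters, shuffling and dropout
    derive from ``config.seed``, so training history is reproducible.

    Attributes (after fit)
    ----------------------
    classes_ : ndarray of class labels in fixed order
    history_ : dict with per-epoch ``loss`` and ``accuracy`` lists
    """

    def __init__(self, config: GestureNetConfig | None = None):
        self.config = config

    # -- internals ------------------------------------------------------

    def _build(self, cfg: GestureNetConfig) -> None:
        rng = np.random.default_rng(cfg.seed)
        maps, kernels, pools = cfg.conv_maps, cfg.conv_kernels, cfg.pool_sizes
        stack = []
        cin = 1
        for i, (m, k) in enumerate(zip(maps, kernels)):
            stack.append(_ConvTime(cin, m, k, rng))
            stack.append(_ReLU())
            if i < len(pools):
                stack.append(_MaxPoolTime(pools[i]))
            cin = m
        self._conv_stack = stack
        fused_dim = cfg.flat_dim() + 3 * WINDOW_CHANNELS
        self._fc1 = _Dense(fused_dim, cfg.fc_width, rng)
        self._fc_relu = _ReLU()
        self._dropout = _Dropout(cfg.dropout_rate)
        self._fc2 = _Dense(cfg.fc_width, cfg.n_classes, rng)
        self._rng = rng

    def _conv_forward(self, windows: np.ndarray, train: bool = False) -> np.ndarray:
        """(n, 8, 200) -> terminal maps (n, maps, length, channels)."""
        x = np.ascontiguousarray(windows.transpose(0, 2, 1)[:, None, :, :], dtype=np.float32)
        for layer in self._conv_stack:
            x = layer.forward(x, train)
        return x

    def _hand_matrix(self, windows: np.ndarray, fs: float) -> np.ndarray:
        feats = np.stack([handcrafted_features(w, fs=fs) for w in windows])
        # bring the frequency features (Hz) onto the same O(1) scale as RMS
        feats = feats.reshape(len(windows), WINDOW_CHANNELS, 3).copy()
        feats[:, :, 1:] /= fs / 2.0
        return feats.reshape(len(windows), -1).astype(np.float32)

    def _forward(self, windows: np.ndarray, train: bool) -> np.ndarray:
        cfg = self.config_
        maps = self._conv_forward(windows, train)
        flat = maps.reshape(len(windows), -1)
        fused = np.concatenate([flat, self._hand_matrix(windows, cfg.fs)], axis=1)
        h = self._fc1.forward(fused, train)
        h = self._fc_relu.forward(h, train)
        h = self._dropout.forward(h, train, self._rng)
        return self._fc2.forward(h, train)

    def _backward(self, dlogits: np.ndarray) -> None:
        d = self._fc2.backward(dlogits)
        d = self._dropout.backward(d)
        d = self._fc_relu.backward(d)
        d = self._fc1.backward(d)
        cfg = self.config_
        n = dlogits.shape[0]
        dmaps = d[:, : cfg.flat_dim()].reshape((n,) + cfg.conv_output_shape())
        x = np.ascontiguousarray(dmaps, dtype=np.float32)
        for layer in reversed(self._conv_stack):
            x = layer.backward(x)

    def _sgd_step(self, lr: float) -> None:
        for layer in [self._fc1, self._fc2] + [
            l for l in self._conv_stack if isinstance(l, _ConvTime)
        ]:
            layer.W -= lr * layer.dW
            layer.b -= lr * layer.db

    # -- sklearn API ----------------------------------------------------

    def fit(self, X, y) -> "HybridGestureClassifier":
        X, y = _as_window_arrays(X, y)
        cfg = self.config if self.config is not None else GestureNetConfig()
        self.config_ = cfg
        labels = np.unique(y)
        if len(labels) < 2:
            raise ValueError("training set must contain at least 2 classes")
        self.classes_ = np.array([c for c in CLASSES if c in labels] + sorted(set(labels) - set(CLASSES)))
        class_idx = {c: i for i, c in enumerate(self.classes_)}
        yi = np.array([class_idx[v] for v in y])
        if cfg.n_classes < len(self.classes_):
            raise ValueError("config.n_classes smaller than number of observed classes")

        self._build(cfg)
        n = len(X)
        history = {"loss": [], "accuracy": []}
        for _epoch in range(cfg.epochs):
            order = self._rng.permutation(n)
            ep_loss = 0.0
            ep_correct = 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                logits = self._forward(X[idx], train=True)
                probs = _softmax(logits)
                batch = len(idx)
                eps = 1e-12
                ep_loss += -float(np.log(probs[np.arange(batch), yi[idx]] + eps).sum())
                ep_correct += int((probs.argmax(axis=1) == yi[idx]).sum())
                dlogits = (probs - np.eye(cfg.n_classes, dtype=np.float32)[yi[idx]]) / batch
                self._backward(dlogits.astype(np.float32))
                self._sgd_step(cfg.learning_rate)
            history["loss"].append(ep_loss / n)
            history["accuracy"].append(ep_correct / n)
        self.history_ = history
        self.n_features_in_ = WINDOW_CHANNELS * WINDOW_SAMPLES
        return self

    def _ensure_model(self) -> None:
        if not hasattr(self, "config_"):
            warnings.warn(
                "predicting with an untrained model: using freshly initialised weights",
                stacklevel=3,
            )
            self.config_ = self.config if self.config is not None else GestureNetConfig()
            self.classes_ = np.array(CLASSES[: self.config_.n_classes])
            self._build(self.config_)
            self.history_ = {"loss": [], "accuracy": []}

    def predict_proba(self, X) -> np.ndarray:
        self._ensure_model()
        X, _ = _as_window_arrays(X, None)
        return _softmax(self._forward(X, train=False)).astype(float)

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        return self.classes_[probs.argmax(axis=1)]  # argmax ties -> lowest class index

    def score(self, X, y) -> float:
        X, y = _as_window_arrays(X, y)
        return float(np.mean(self.predict(X) == y))

    # -- persistence ----------------------------------------------------

    def save(self, path_prefix) -> None:
        """Write ``<prefix>.json`` metadata and ``<prefix>.npz`` parameters."""
        self._ensure_model()
        prefix = Path(path_prefix)
        meta = {"config": asdict(self.config_), "classes": list(map(str, self.classes_)),
                "history": self.history_}
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))
        arrays = {}
        for i, layer in enumerate(self._conv_stack):
            if isinstance(layer, _ConvTime):
                arrays[f"conv{i}_W"], arrays[f"conv{i}_b"] = layer.W, layer.b
        arrays["fc1_W"], arrays["fc1_b"] = self._fc1.W, self._fc1.b
        arrays["fc2_W"], arrays["fc2_b"] = self._fc2.W, self._fc2.b
        np.savez(prefix.with_suffix(".npz"), **arrays)

    @classmethod
    def load(cls, path_prefix) -> "HybridGestureClassifier":
        prefix = Path(path_prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        cfgd = meta["config"]
        for key in ("conv_maps", "conv_kernels", "pool_sizes"):
            cfgd[key] = tuple(cfgd[key])
        model = cls(config=GestureNetConfig(**cfgd))
        model.config_ = model.config
        model.classes_ = np.array(meta["classes"])
        model.history_ = meta["history"]
        model._build(model.config_)
        blob = np.load(prefix.with_suffix(".npz"))
        for i, layer in enumerate(model._conv_stack):
            if isinstance(layer, _ConvTime):
                layer.W, layer.b = blob[f"conv{i}_W"], blob[f"conv{i}_b"]
        model._fc1.W, model._fc1.b = blob["fc1_W"], blob["fc1_b"]
        model._fc2.W, model._fc2.b = blob["fc2_W"], blob["fc2_b"]
        return model


def _as_window_arrays(X, y):
    if isinstance(X, GestureDataset):
        return X.windows, X.labels
    if len(X) and isinstance(X[0], GestureWindow):
        arr = np.stack([w.values for w in X])
        labels = np.array([w.label for w in X]) if y is None else np.asarray(y)
        return arr, labels
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[None]
    return X, (None if y is None else np.asarray(y))


# ----------------------------------------------------------------------
# module-level operations (thin wrappers over the estimator)
# ----------------------------------------------------------------------


def conv_feature_extract(
    windows, model: HybridGestureClassifier | None = None, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Run the time-only conv stack; returns (maps, flattened vectors).

    With the reference configuration a batch of n windows yields maps of
    shape (n, 128, 5, 8) and flattened vectors of length 5120.  If no model
    is given a freshly initialised (untrained) stack with ``seed`` is used —
    the shape and channel-independence contracts hold for any weights.
    """
    X, _ = _as_window_arrays(windows, None)
    if model is None:
        model = HybridGestureClassifier(GestureNetConfig(seed=seed))
        model.config_ = model.config
        model._build(model.config)
    maps = model._conv_forward(X, train=False).astype(float)
    return maps, maps.reshape(len(X), -1)


def train_gesture(dataset: GestureDataset, config: GestureNetConfig | None = None) -> HybridGestureClassifier:
    """Fit the hybrid classifier on a labelled dataset."""
    return HybridGestureClassifier(config).fit(dataset.windows, dataset.labels)


def predict_gesture(model: HybridGestureClassifier, window) -> tuple[str, np.ndarray]:
    """Classify one window; returns (label, score vector summing to 1)."""
    probs = model.predict_proba([window.values if isinstance(window, GestureWindow) else window])[0]
    return str(model.classes_[int(probs.argmax())]), probs


def evaluate_confusion(model: HybridGestureClassifier, dataset: GestureDataset) -> ConfusionMatrix:
    """Confusion matrix of the model on a labelled dataset."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    pred = model.predict(dataset.windows)
    k = len(CLASSES)
    counts = np.zeros((k, k), dtype=int)
    for t, p in zip(dataset.labels, pred):
        counts[_CLASS_INDEX[t], _CLASS_INDEX[p]] += 1
    return ConfusionMatrix(counts)
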