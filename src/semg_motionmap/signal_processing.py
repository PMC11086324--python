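"""Raw sEMG conditioning and time-domain feature extraction.

Surface EMG picked up by skin electrodes is a band-limited stochastic
interference pattern (useful energy roughly 20-200 Hz) contaminated by
low-frequency motion artifact, 50 Hz mains hum, and wide-band sensor noise.
This module cleans the raw signal with a zero-phase Butterworth/notch chain,
extracts the two standard amplitude features (mean absolute value and root
mean square) on sliding windows, smooths them with a moving average, and
min-max normalises them to [0, 1] so that recordings from different sessions
are comparable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "EmgRecording",
    "FilterStage",
    "FilterChain",
    "FeatureSeries",
    "IntervalScaler",
    "design_filter_chain",
    "apply_filter_chain",
    "moving_average",
    "mav",
    "rms",
    "sliding_features",
    "fit_interval_scaling",
    "interval_scale",
    "read_signal_csv",
    "write_signal_csv",
]


@dataclass
class EmgRecording:
    """Multi-channel sampled signal.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal values (arbitrary voltage scale).
    fs : float
        Sampling rate in Hz, > 0.
    channel_names : list of str, optional
        Ordered channel labels; defaults to ``ch1..chK``.
    """

    samples: np.ndarray
    fs: float
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.shape[0] < 1 or self.samples.shape[1] < 1:
            raise ValueError("recording must have >= 1 channel and >= 1 sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")
        if self.channel_names is None:
            self.channel_names = [f"ch{i + 1}" for i in range(self.n_channels)]
        elif len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class FilterStage:
    """One IIR stage: ``kind`` in {highpass, lowpass, notch}; ``q`` for notch only."""

    kind: str
    cutoff: float
    order: int = 4
    q: float | None = None

    def sos(self, fs: float) -> np.ndarray:
        """Second-order sections of this stage designed for rate ``fs``."""
        if self.kind in ("highpass", "lowpass"):
            return sps.butter(self.order, self.cutoff, btype=self.kind, fs=fs, output="sos")
        if self.kind == "notch":
            b, a = sps.iirnotch(self.cutoff, self.q if self.q is not None else 30.0, fs=fs)
            return sps.tf2sos(b, a)
        raise ValueError(f"unknown filter stage kind {self.kind!r}")


@dataclass
class FilterChain:
    """Ordered filter stages plus the sampling rate they were designed for."""

    stages: list[FilterStage]
    fs: float

    def sos(self) -> np.ndarray:
        if not self.stages:
            return np.empty((0, 6))
        return np.vstack([st.sos(self.fs) for st in self.stages])

    def frequency_response(self, freqs: np.ndarray) -> np.ndarray:
        """Complex response of the chain (single forward pass) at ``freqs`` Hz."""
        if not self.stages:
            return np.ones_like(np.asarray(freqs, dtype=float), dtype=complex)
        _, h = sps.sosfreqz(self.sos(), worN=np.asarray(freqs, dtype=float), fs=self.fs)
        return h

    def to_json(self) -> str:
        return json.dumps(
            {
                "fs": self.fs,
                "stages": [
                    {"kind": s.kind, "cutoff": s.cutoff, "order": s.order, "q": s.q}
                    for s in self.stages
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FilterChain":
        d = json.loads(text)
        return cls(
            stages=[FilterStage(s["kind"], s["cutoff"], s.get("order", 4), s.get("q")) for s in d["stages"]],
            fs=d["fs"],
        )


@dataclass
class FeatureSeries:
    """Windowed per-channel amplitude features.

    ``frames`` has shape (n_channels, n_frames); ``frame_times`` are the
    window-centre times in seconds.
    """

    frames: np.ndarray
    frame_times: np.ndarray
    feature_kind: str = "RMS"
    window_ms: float = 0.0
    step_ms: float = 0.0
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=float))
        self.frame_times = np.asarray(self.frame_times, dtype=float)

    @property
    def n_channels(self) -> int:
        return self.frames.shape[0]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[1]


def design_filter_chain(
    fs: float,
    low_cut: float = 20.0,
    high_cut: float = 200.0,
    notch_freq: float = 50.0,
    order: int = 4,
    notch_q: float = 30.0,
    literal_lowpass: bool = False,
) -> FilterChain:
    """Design the standard sEMG conditioning chain.

    The chain is a ``low_cut`` high-pass (motion-artifact removal), a
    ``high_cut`` low-pass (wide-band noise), and a mains notch at
    ``notch_freq``.  Any stage whose cutoff reaches the Nyquist rate is
    dropped with a warning; a zero/None cutoff omits that stage.

    ``literal_lowpass=True`` builds the artifact stage as a second low-pass
    at ``low_cut`` instead of a high-pass.  That variant follows a common
    textual description of the chain but destroys the EMG band, so the
    high-pass is the default.
    """
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    nyq = fs / 2.0
    stages: list[FilterStage] = []

    def _add(kind: str, cutoff: float | None, q: float | None = None) -> None:
        if cutoff is None or cutoff <= 0:
            return
        if cutoff >= nyq:
            warnings.warn(
                f"{kind} stage at {cutoff} Hz dropped: cutoff >= Nyquist ({nyq} Hz)",
                stacklevel=3,
            )
            return
        stages.append(FilterStage(kind, cutoff, order=order, q=q))

    _add("lowpass" if literal_lowpass else "highpass", low_cut)
    _add("lowpass", high_cut)
    _add("notch", notch_freq, q=notch_q)
    return FilterChain(stages=stages, fs=fs)


def apply_filter_chain(rec: EmgRecording, chain: FilterChain) -> EmgRecording:
    """Apply ``chain`` forward-backward (zero phase) to every channel."""
    if not np.isclose(chain.fs, rec.fs):
        raise ValueError(f"chain designed for fs={chain.fs} but recording has fs={rec.fs}")
    if not chain.stages:
        return EmgRecording(rec.samples.copy(), rec.fs, list(rec.channel_names))
    out = sps.sosfiltfilt(chain.sos(), rec.samples, axis=1)
    return EmgRecording(out, rec.fs, list(rec.channel_names))


def moving_average(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Boxcar smoother with left-edge hold.

    The first full-window mean is replicated over the first
    ``window_samples - 1`` positions so the output length equals the input
    length; a constant series is preserved exactly.
    """
    x = np.asarray(x, dtype=float)
    if window_samples < 1:
        raise ValueError("window_samples must be >= 1")
    n = x.shape[-1]
    if window_samples > n:
        raise ValueError(f"window ({window_samples}) larger than signal ({n})")
    if window_samples == 1:
        return x.copy()
    kernel = np.ones(window_samples) / window_samples
    valid = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="valid"), -1, x)
    pad = np.repeat(valid[..., :1], window_samples - 1, axis=-1)
    return np.concatenate([pad, valid], axis=-1)


def mav(x: np.ndarray) -> float:
    """Mean absolute value of a window: (1/N) * sum |x_i|."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    return float(np.mean(np.abs(x)))


def rms(x: np.ndarray) -> float:
    """Root mean square of a window: sqrt((1/N) * sum x_i^2)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    return float(np.sqrt(np.mean(np.square(x))))


_FEATURE_FUNCS = {"MAV": mav, "RMS": rms}


def sliding_features(
    rec: EmgRecording, window_ms: float, step_ms: float, kind: str = "RMS"
) -> FeatureSeries:
    """Frame the recording and compute MAV or RMS per window per channel.

    Produces ``floor((N - w) / s) + 1`` frames; frame times are window
    centres.
    """
    kind = kind.upper()
    if kind not in _FEATURE_FUNCS:
        raise ValueError(f"feature kind must be MAV or RMS, got {kind!r}")
    w = int(round(window_ms * rec.fs / 1000.0))
    s = int(round(step_ms * rec.fs / 1000.0))
    if w < 1 or s < 1:
        raise ValueError("window and step must be at least one sample")
    if w > rec.n_samples:
        raise ValueError(f"window ({w} samples) exceeds recording length ({rec.n_samples})")
    n_frames = (rec.n_samples - w) // s + 1
    starts = np.arange(n_frames) * s
    # vectorised: gather strided windows, reduce along the window axis
    idx = starts[:, None] + np.arange(w)[None, :]
    windows = rec.samples[:, idx]  # (C, n_frames, w)
    if kind == "MAV":
        frames = np.mean(np.abs(windows), axis=2)
    else:
        frames = np.sqrt(np.mean(np.square(windows), axis=2))
    frame_times = (starts + (w - 1) / 2.0) / rec.fs
    return FeatureSeries(
        frames=frames,
        frame_times=frame_times,
        feature_kind=kind,
        window_ms=window_ms,
        step_ms=step_ms,
        channel_names=list(rec.channel_names),
    )


class IntervalScaler:
    """Per-channel min-max normalisation of feature frames to [0, 1].

    Interval scaling removes session-to-session amplitude differences: the
    fitted minimum maps to 0 and the maximum to 1.  At transform time values
    outside the fitted range are clamped into [0, 1] (new sessions can
    exceed the training extremes).  Follows the sklearn fit/transform
    protocol; operates on arrays of shape (n_channels, n_frames).
    """

    def __init__(self, clip: bool = True):
        self.clip = clip

    def fit(self, X: np.ndarray | FeatureSeries, y=None) -> "IntervalScaler":
        X = X.frames if isinstance(X, FeatureSeries) else np.atleast_2d(np.asarray(X, dtype=float))
        x_min = X.min(axis=1)
        x_max = X.max(axis=1)
        degenerate = np.nonzero(~(x_max > x_min))[0]
        if degenerate.size:
            raise ValueError(
                f"degenerate (constant) channel(s) {degenerate.tolist()}: x_max must exceed x_min"
            )
        self.x_min_ = x_min
        self.x_max_ = x_max
        self.n_channels_ = X.shape[0]
        return self

    def transform(self, X: np.ndarray | FeatureSeries):
        is_series = isinstance(X, FeatureSeries)
        arr = X.frames if is_series else np.atleast_2d(np.asarray(X, dtype=float))
        if arr.shape[0] != self.n_channels_:
            raise ValueError(
                f"channel mismatch: fitted on {self.n_channels_} channels, got {arr.shape[0]}"
            )
        out = (arr - self.x_min_[:, None]) / (self.x_max_ - self.x_min_)[:, None]
        if self.clip:
            out = np.clip(out, 0.0, 1.0)
        if is_series:
            return FeatureSeries(
                out, X.frame_times, X.feature_kind, X.window_ms, X.step_ms, X.channel_names
            )
        return out

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        arr = np.atleast_2d(np.asarray(X, dtype=float))
        return arr * (self.x_max_ - self.x_min_)[:, None] + self.x_min_[:, None]

    def get_params(self, deep: bool = True) -> dict:
        return {"clip": self.clip}

    def set_params(self, **params) -> "IntervalScaler":
        for k, v in params.items():
            setattr(self, k, v)
        return self


def fit_interval_scaling(features: FeatureSeries | np.ndarray) -> IntervalScaler:
    """Fit per-channel min/max normalisation parameters."""
    return IntervalScaler().fit(features)


def interval_scale(features: FeatureSeries, scaler: IntervalScaler) -> FeatureSeries:
    """Apply fitted interval scaling: x' = (x - x_min) / (x_max - x_min)."""
    return scaler.transform(features)


def read_signal_csv(path, max_jitter: float = 0.01) -> EmgRecording:
    """Read a ``time_s, ch1..chK`` CSV into an EmgRecording.

    The time column must be uniformly sampled within ``max_jitter`` relative
    deviation of the median step.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("signal CSV needs a time column and at least one channel")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("signal CSV needs at least two samples")
    dt = np.diff(t)
    med = np.median(dt)
    if med <= 0 or np.any(np.abs(dt - med) > max_jitter * med):
        raise ValueError("non-uniform sampling in signal CSV (jitter above 1%)")
    return EmgRecording(
        samples=df.iloc[:, 1:].to_numpy(dtype=float).T,
        fs=1.0 / med,
        channel_names=list(df.columns[1:]),
    )


def write_signal_csv(rec: EmgRecording, path) -> None:
    df = pd.DataFrame(rec.samples.T, columns=rec.channel_names)
    df.insert(0, "time_s", rec.times)
    df.to_csv(path, index=False)
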