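"""Sliding-window time-domain sEMG features.

Streams are segmented with a continuous sliding window (default 180 ms length,
40 ms increment) and each window of each channel yields the four standard
myoelectric time-domain features, in fixed order:

* MAV — mean absolute value;
* ZC  — zero crossings (sign changes exceeding an amplitude threshold);
* SSC — slope sign changes (local extrema exceeding a slope threshold);
* WL  — waveform length (summed absolute first difference).

A trial with n channels therefore produces a 4n-dimensional feature vector per
window. Each window also carries its majority phase label, the joint angle at
the window end, and the angle one prediction horizon ahead (default 40 ms,
matching the window increment so a prediction lines up with the next incoming
window).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as _sig

from .io import AlignedTrial
from .simulate import PHASES


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry. Sample counts are rounded from milliseconds."""

    length_ms: float = 180.0
    increment_ms: float = 40.0
    fs: float = 1111.11

    def __post_init__(self) -> None:
        if self.length_samples <= self.increment_samples or self.increment_samples <= 0:
            raise ValueError("require length_samples > increment_samples > 0")

    @property
    def length_samples(self) -> int:
        return int(round(self.length_ms * self.fs / 1000.0))

    @property
    def increment_samples(self) -> int:
        return int(round(self.increment_ms * self.fs / 1000.0))


def window_count(n_samples: int, spec: WindowSpec) -> int:
    """Number of full windows in a stream: floor((N - L) / inc) + 1."""
    if n_samples < spec.length_samples:
        warnings.warn("stream shorter than one window; zero windows")
        return 0
    return (n_samples - spec.length_samples) // spec.increment_samples + 1


FEATURE_ORDER = ("mav", "zc", "ssc", "wl")


def td_features(
    segment: np.ndarray, zc_threshold: float = 0.0, ssc_threshold: float = 0.0
) -> tuple[float, float, float, float]:
    """(MAV, ZC, SSC, WL) of one 1-D segment.

    ZC counts sign products x_k * x_{k+1} < 0 with |x_k - x_{k+1}| >= zc_threshold;
    SSC counts interior samples with (x_k - x_{k-1})(x_k - x_{k+1}) > 0 and at
    least one neighbouring step >= ssc_threshold.
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 3:
        raise ValueError("segment must have at least 3 samples")
    m = _windowed_features(x[None, :], zc_threshold, ssc_threshold)[0]
    return tuple(float(v) for v in m)


def _windowed_features(W: np.ndarray, zc_thr: float, ssc_thr: float) -> np.ndarray:
    """Vectorised features for a stack of windows, shape (n_windows, L) -> (n, 4)."""
    mav = np.abs(W).mean(axis=1)
    d = np.diff(W, axis=1)
    zc = np.sum((W[:, :-1] * W[:, 1:] < 0) & (np.abs(d) >= zc_thr), axis=1)
    left = W[:, 1:-1] - W[:, :-2]
    right = W[:, 1:-1] - W[:, 2:]
    ssc = np.sum(
        (left * right > 0)
        & ((np.abs(left) >= ssc_thr) | (np.abs(right) >= ssc_thr)),
        axis=1,
    )
    wl = np.abs(d).sum(axis=1)
    return np.column_stack([mav, zc, ssc, wl]).astype(float)


@dataclass
class FeatureFrame:
    """Windowed feature matrix with aligned labels and angle targets.

    ``X`` is (n_windows, 4n) with the per-channel block order
    (MAV, ZC, SSC, WL); ``times`` are window end-times in seconds.
    """

    times: np.ndarray
    X: np.ndarray
    channel_names: tuple[str, ...]
    phase: np.ndarray
    angle_now: np.ndarray
    angle_future: np.ndarray
    horizon_ms: float = 40.0
    increment_ms: float = 40.0
    condition: str = "noExo"
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def feature_names(self) -> list[str]:
        return [f"{f}_{ch}" for ch in self.channel_names for f in FEATURE_ORDER]

    def __len__(self) -> int:
        return len(self.times)

    def slice(self, start: int, stop: int) -> "FeatureFrame":
        """Contiguous window range as a new frame (keeps time order)."""
        return FeatureFrame(
            times=self.times[start:stop],
            X=self.X[start:stop],
            channel_names=self.channel_names,
            phase=self.phase[start:stop],
            angle_now=self.angle_now[start:stop],
            angle_future=self.angle_future[start:stop],
            horizon_ms=self.horizon_ms,
            increment_ms=self.increment_ms,
            condition=self.condition,
            meta=dict(self.meta),
        )


def build_feature_frame(
    aligned: AlignedTrial,
    channels: list[str] | tuple[str, ...] | None = None,
    spec: WindowSpec | None = None,
    horizon_ms: float = 40.0,
    zc_threshold: float = 0.0,
    ssc_threshold: float = 0.0,
    prefilter: bool = True,
    bandpass_hz: tuple[float, float] = (20.0, 450.0),
) -> FeatureFrame:
    """Window an aligned trial into a :class:`FeatureFrame`.

    Features are computed on the band-passed raw sEMG (standard myoelectric
    practice), not on the activation envelope. Windows whose future-angle
    query time falls beyond the recorded angle trace are dropped.
    """
    if spec is None:
        spec = WindowSpec(fs=aligned.fs_emg)
    names = tuple(channels) if channels is not None else aligned.channel_names
    idx = []
    for name in names:
        if name not in aligned.channel_names:
            raise KeyError(f"unknown channel name {name!r}")
        idx.append(aligned.channel_names.index(name))
    emg = aligned.emg[idx]
    if prefilter:
        hi = min(bandpass_hz[1], 0.99 * aligned.fs_emg / 2)
        sos = _sig.butter(4, [bandpass_hz[0], hi], btype="bandpass",
                          fs=aligned.fs_emg, output="sos")
        emg = _sig.sosfiltfilt(sos, emg, axis=1)

    L, inc = spec.length_samples, spec.increment_samples
    n = emg.shape[1]
    count = window_count(n, spec)
    if count == 0:
        raise ValueError("trial too short for a single window")
    starts = np.arange(count) * inc
    ends = starts + L
    t_end = ends / aligned.fs_emg
    h_s = horizon_ms / 1000.0
    keep = t_end + h_s <= aligned.duration_s + 1e-9
    starts, ends, t_end = starts[keep], ends[keep], t_end[keep]

    blocks = []
    for ch in range(emg.shape[0]):
        W = sliding_window_view(emg[ch], L)[::inc][: len(starts)]
        blocks.append(_windowed_features(W, zc_threshold, ssc_threshold))
    X = np.hstack(blocks)

    Wlab = sliding_window_view(aligned.phase, L)[::inc][: len(starts)]
    phase = np.array(
        [np.bincount(w, minlength=4).argmax() for w in Wlab], dtype=np.int8
    )
    angle_now = aligned.angle_at(t_end)
    angle_future = aligned.angle_at(t_end + h_s)
    return FeatureFrame(
        times=t_end,
        X=X,
        channel_names=names,
        phase=phase,
        angle_now=angle_now,
        angle_future=angle_future,
        horizon_ms=horizon_ms,
        increment_ms=spec.increment_ms,
        condition=aligned.condition,
        meta=dict(aligned.meta),
    )


def save_feature_frame(frame: FeatureFrame, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=frame.times)
        f.create_dataset("X", data=frame.X)
        f.create_dataset("phase", data=frame.phase)
        f.create_dataset("angle_now", data=frame.angle_now)
        f.create_dataset("angle_future", data=frame.angle_future)
        f.create_dataset(
            "channel_names", data=np.array(frame.channel_names, dtype="S16")
        )
        f.attrs["horizon_ms"] = frame.horizon_ms
        f.attrs["increment_ms"] = frame.increment_ms
        f.attrs["condition"] = frame.condition


def load_feature_frame(path) -> FeatureFrame:
    with h5py.File(path, "r") as f:
        return FeatureFrame(
            times=f["times"][()],
            X=f["X"][()],
            channel_names=tuple(n.decode() for n in f["channel_names"][()]),
            phase=f["phase"][()],
            angle_now=f["angle_now"][()],
            angle_future=f["angle_future"][()],
            horizon_ms=float(f.attrs["horizon_ms"]),
            increment_ms=float(f.attrs["increment_ms"]),
            condition=str(f.attrs["condition"]),
        )


def frame_to_dataframe(frame: FeatureFrame):
    """Feature frame as a tidy pandas DataFrame (CSV-friendly)."""
    import pandas as pd

    df = pd.DataFrame(frame.X, columns=frame.feature_names)
    df.insert(0, "time_s", frame.times)
    df["phase"] = [PHASES[k] for k in frame.phase]
    df["angle_now_deg"] = frame.angle_now
    df["angle_future_deg"] = frame.angle_future
    return df
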