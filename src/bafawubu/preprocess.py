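"""Signal conditioning: 5 Hz low-pass, 50 Hz downsampling, 2 s windowing.

The processing chain mirrors the deployed recognizer: raw six-axis streams
are low-pass filtered at 5 Hz to remove high-frequency noise while keeping
the sub-2 Hz movement content, downsampled to 50 Hz (the common smartphone
IMU rate), and segmented into 2 s windows with 50 % overlap, giving
100-sample x 6-channel windows at a 1 s hop.

Transformers follow the scikit-learn estimator protocol and operate on bare
arrays; the module-level functions wrap them for :class:`ImuStream` /
:class:`WindowedDataset` plumbing.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
import warnings
from collections import Counter

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from bafawubu.exceptions import InsufficientDataError
from bafawubu.movements import TRANSITION_LABEL
from bafawubu.simulate import ImuStream

DEFAULT_CUTOFF_HZ = 5.0
DEFAULT_TARGET_RATE_HZ = 50.0
DEFAULT_WINDOW_S = 2.0
DEFAULT_OVERLAP = 0.5

#: Floor applied to a zero-variance channel's standard deviation.
SD_FLOOR = 1e-8


@dataclasses.dataclass(frozen=True)
class FilterSpec:
    """Low-pass filter configuration (Butterworth)."""

    cutoff_hz: float = DEFAULT_CUTOFF_HZ
    order: int = 4
    zero_phase: bool = True


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    """Segmentation configuration: 2 s windows, 50 % overlap at 50 Hz."""

    length_s: float = DEFAULT_WINDOW_S
    overlap_frac: float = DEFAULT_OVERLAP
    rate_hz: float = DEFAULT_TARGET_RATE_HZ

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_frac < 1.0:
            raise ValueError("overlap_frac must be in [0, 1)")
        if abs(self.length_s * self.rate_hz - round(self.length_s * self.rate_hz)) > 1e-9:
            raise ValueError("length_s x rate_hz must be an integer sample count")

    @property
    def length(self) -> int:
        """Window length in samples (default 100)."""
        return int(round(self.length_s * self.rate_hz))

    @property
    def hop(self) -> int:
        """Hop between window starts in samples (default 50)."""
        hop = int(round(self.length * (1.0 - self.overlap_frac)))
        return max(hop, 1)


@dataclasses.dataclass
class WindowedDataset:
    """Fixed-length labelled windows: (m, L, 6) array + m class codes."""

    windows: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray | None = None
    channel_stats: "ChannelStandardizer | None" = None

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        if self.windows.ndim != 3:
            raise ValueError("windows must be (m, length, channels)")
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != len(self.windows):
            raise ValueError("labels must have one entry per window")
        if self.subject_ids is not None:
            self.subject_ids = np.asarray(self.subject_ids, dtype=object)
            if len(self.subject_ids) != len(self.windows):
                raise ValueError("subject_ids must have one entry per window")

    def __len__(self) -> int:
        return len(self.windows)

    def subset(self, idx: np.ndarray) -> "WindowedDataset":
        return WindowedDataset(
            windows=self.windows[idx],
            labels=self.labels[idx],
            subject_ids=None if self.subject_ids is None else self.subject_ids[idx],
            channel_stats=self.channel_stats,
        )

    def save(self, directory: str | pathlib.Path) -> None:
        """Persist as ``windows.npy`` + ``labels.csv`` (+ stats JSON)."""
        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.save(directory / "windows.npy", self.windows)
        frame = pd.DataFrame({
            "window_index": np.arange(len(self)),
            "class": self.labels,
        })
        if self.subject_ids is not None:
            frame["subject_id"] = self.subject_ids
        frame.to_csv(directory / "labels.csv", index=False)
        if self.channel_stats is not None and self.channel_stats._is_fitted():
            stats = {"mean": self.channel_stats.mean_.tolist(),
                     "sd": self.channel_stats.sd_.tolist()}
            (directory / "channel_stats.json").write_text(json.dumps(stats))

    @classmethod
    def load(cls, directory: str | pathlib.Path) -> "WindowedDataset":
        directory = pathlib.Path(directory)
        windows = np.load(directory / "windows.npy")
        frame = pd.read_csv(directory / "labels.csv")
        subject_ids = (frame["subject_id"].to_numpy(dtype=object)
                       if "subject_id" in frame.columns else None)
        stats = None
        stats_path = directory / "channel_stats.json"
        if stats_path.exists():
            payload = json.loads(stats_path.read_text())
            stats = ChannelStandardizer()
            stats.mean_ = np.asarray(payload["mean"], dtype=float)
            stats.sd_ = np.asarray(payload["sd"], dtype=float)
        return cls(windows=windows, labels=frame["class"].to_numpy(dtype=object),
                   subject_ids=subject_ids, channel_stats=stats)


class LowPassFilter(BaseEstimator, TransformerMixin):
    """Butterworth low-pass over the time axis of an (n, channels) array.

    Defaults to 4th order at 5 Hz applied forward-backward (``filtfilt``),
    i.e. zero phase: waveform timing is preserved, which matters because
    windows are cut on the filtered signal.  DC gain is exactly 1.
    """

    def __init__(self, rate_hz: float = 200.0, cutoff_hz: float = DEFAULT_CUTOFF_HZ,
                 order: int = 4, zero_phase: bool = True):
        self.rate_hz = rate_hz
        self.cutoff_hz = cutoff_hz
        self.order = order
        self.zero_phase = zero_phase

    def fit(self, X=None, y=None):  # stateless
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not 0 < self.cutoff_hz < self.rate_hz / 2:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz must lie in (0, Nyquist="
                f"{self.rate_hz / 2} Hz)")
        X = np.asarray(X, dtype=float)
        sos = sps.butter(self.order, self.cutoff_hz, btype="low",
                         fs=self.rate_hz, output="sos")
        if self.zero_phase:
            return sps.sosfiltfilt(sos, X, axis=0)
        return sps.sosfilt(sos, X, axis=0)


class Resampler(BaseEstimator, TransformerMixin):
    """Downsample an (n, channels) array from ``source_hz`` to ``target_hz``.

    Plain decimation (every k-th sample) when the ratio is an integer —
    safe because the caller guarantees content below target_hz / 2 — and
    polyphase rational resampling otherwise.
    """

    def __init__(self, source_hz: float, target_hz: float = DEFAULT_TARGET_RATE_HZ):
        self.source_hz = source_hz
        self.target_hz = target_hz

    def fit(self, X=None, y=None):
        return self

    def _ratio(self) -> tuple[int, int]:
        from fractions import Fraction
        frac = Fraction(self.target_hz / self.source_hz).limit_denominator(1000)
        return frac.numerator, frac.denominator

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.target_hz > self.source_hz:
            raise ValueError("target rate must not exceed source rate")
        X = np.asarray(X, dtype=float)
        if self.target_hz == self.source_hz:
            return X.copy()
        step = self.source_hz / self.target_hz
        if abs(step - round(step)) < 1e-9:
            return X[:: int(round(step))].copy()
        up, down = self._ratio()
        return sps.resample_poly(X, up, down, axis=0)

    def index_map(self, n_source: int) -> np.ndarray:
        """Source index of each output sample (nearest-sample mapping),
        used to carry per-sample labels through resampling."""
        step = self.source_hz / self.target_hz
        if abs(step - round(step)) < 1e-9:
            return np.arange(0, n_source, int(round(step)))
        up, down = self._ratio()
        n_out = int(np.ceil(n_source * up / down))
        src = np.round(np.arange(n_out) * down / up).astype(int)
        return np.clip(src, 0, n_source - 1)


class WindowSegmenter(BaseEstimator, TransformerMixin):
    """Cut an (n, channels) array into overlapping contiguous windows.

    Produces ``floor((n - L) / H) + 1`` windows of L samples at hop H
    (defaults L = 100, H = 50 at 50 Hz: 2 s windows, 50 % overlap).
    """

    def __init__(self, length_s: float = DEFAULT_WINDOW_S,
                 overlap_frac: float = DEFAULT_OVERLAP,
                 rate_hz: float = DEFAULT_TARGET_RATE_HZ):
        self.length_s = length_s
        self.overlap_frac = overlap_frac
        self.rate_hz = rate_hz

    def _spec(self) -> WindowSpec:
        return WindowSpec(self.length_s, self.overlap_frac, self.rate_hz)

    def fit(self, X=None, y=None):
        return self

    def n_windows(self, n_samples: int) -> int:
        spec = self._spec()
        if n_samples < spec.length:
            raise InsufficientDataError(
                f"stream of {n_samples} samples is shorter than one "
                f"{spec.length}-sample window")
        return (n_samples - spec.length) // spec.hop + 1

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        spec = self._spec()
        m = self.n_windows(len(X))
        starts = np.arange(m) * spec.hop
        return np.stack([X[s:s + spec.length] for s in starts])


class ChannelStandardizer(BaseEstimator, TransformerMixin):
    """Per-channel z-scoring of windowed data (m, L, channels).

    Accelerometer (g) and gyroscope (°/s) channels differ by orders of
    magnitude; statistics are computed on the training set and stored in the
    model bundle so validation and streaming data are scaled identically.
    A zero-variance channel's sd is floored at 1e-8 (with a warning).
    """

    def __init__(self):
        pass

    def _is_fitted(self) -> bool:
        return hasattr(self, "mean_")

    def fit(self, X: np.ndarray, y=None) -> "ChannelStandardizer":
        X = np.asarray(X, dtype=float)
        axes = tuple(range(X.ndim - 1))
        self.mean_ = X.mean(axis=axes)
        sd = X.std(axis=axes)
        if np.any(sd < SD_FLOOR):
            warnings.warn("zero-variance channel; sd floored at 1e-8",
                          RuntimeWarning, stacklevel=2)
        self.sd_ = np.maximum(sd, SD_FLOOR)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self._is_fitted():
            raise ValueError("ChannelStandardizer must be fitted first")
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) / self.sd_


# ---------------------------------------------------------------------------
# Stream-level wrappers


def low_pass(stream: ImuStream, spec: FilterSpec = FilterSpec()) -> ImuStream:
    """Low-pass filter a stream; length, rate and labels are unchanged."""
    filt = LowPassFilter(rate_hz=stream.rate_hz, cutoff_hz=spec.cutoff_hz,
                         order=spec.order, zero_phase=spec.zero_phase)
    return ImuStream(rate_hz=stream.rate_hz,
                     samples=filt.transform(stream.samples),
                     labels=None if stream.labels is None else stream.labels.copy())


def resample_to(stream: ImuStream,
                target_hz: float = DEFAULT_TARGET_RATE_HZ) -> ImuStream:
    """Downsample a (pre-filtered) stream; labels follow by nearest sample."""
    rs = Resampler(source_hz=stream.rate_hz, target_hz=target_hz)
    samples = rs.transform(stream.samples)
    labels = None
    if stream.labels is not None:
        labels = stream.labels[rs.index_map(len(stream))][: len(samples)]
    return ImuStream(rate_hz=target_hz, samples=samples, labels=labels)


def preprocess_stream(stream: ImuStream,
                      filter_spec: FilterSpec = FilterSpec(),
                      target_hz: float = DEFAULT_TARGET_RATE_HZ) -> ImuStream:
    """Full conditioning chain: low-pass at 5 Hz then downsample to 50 Hz."""
    return resample_to(low_pass(stream, filter_spec), target_hz)


def segment(stream: ImuStream, spec: WindowSpec = WindowSpec()) -> WindowedDataset:
    """Segment a conditioned stream into a :class:`WindowedDataset`.

    Windows carry no labels yet (empty string); apply
    :func:`label_windows` with the stream's per-sample labels.
    """
    if abs(stream.rate_hz - spec.rate_hz) > 1e-9:
        raise ValueError(
            f"stream rate {stream.rate_hz} Hz does not match window spec "
            f"rate {spec.rate_hz} Hz; resample first")
    seg = WindowSegmenter(spec.length_s, spec.overlap_frac, spec.rate_hz)
    windows = seg.transform(stream.samples)
    return WindowedDataset(windows=windows,
                           labels=np.full(len(windows), "", dtype=object))


def label_windows(dataset: WindowedDataset, per_sample_labels: np.ndarray,
                  spec: WindowSpec = WindowSpec()) -> WindowedDataset:
    """Label each window by majority vote over its samples.

    ``"transition"`` samples are excluded from the vote; a 50/50 tie is
    broken by the label of the window's centre sample (falling back to the
    first tied class in canonical order if the centre sample is itself a
    transition); windows containing no class samples at all are dropped.
    """
    per_sample_labels = np.asarray(per_sample_labels, dtype=object)
    L, hop = spec.length, spec.hop
    m = len(dataset)
    needed = (m - 1) * hop + L
    if len(per_sample_labels) < needed:
        raise ValueError(
            f"per-sample labels ({len(per_sample_labels)}) shorter than the "
            f"segmented span ({needed} samples)")
    keep: list[int] = []
    labels: list[str] = []
    for i in range(m):
        window_labels = per_sample_labels[i * hop: i * hop + L]
        votes = Counter(l for l in window_labels if l != TRANSITION_LABEL)
        if not votes:
            continue  # transition-only window
        top = max(votes.values())
        tied = sorted((l for l, c in votes.items() if c == top),
                      key=lambda l: str(l))
        if len(tied) == 1:
            label = tied[0]
        else:
            center = window_labels[L // 2]
            label = center if center in tied else tied[0]
        keep.append(i)
        labels.append(label)
    idx = np.asarray(keep, dtype=int)
    return WindowedDataset(windows=dataset.windows[idx],
                           labels=np.asarray(labels, dtype=object),
                           subject_ids=None if dataset.subject_ids is None
                           else dataset.subject_ids[idx],
                           channel_stats=dataset.channel_stats)


def standardize(dataset: WindowedDataset,
                stats: ChannelStandardizer | None = None) -> WindowedDataset:
    """Z-score a dataset per channel.

    With ``stats=None`` the statistics are computed from the dataset itself
    and stored on the result; otherwise the given (training) statistics are
    applied unchanged.
    """
    if stats is None:
        stats = ChannelStandardizer().fit(dataset.windows)
    return WindowedDataset(windows=stats.transform(dataset.windows),
                           labels=dataset.labels.copy(),
                           subject_ids=dataset.subject_ids,
                           channel_stats=stats)


def windows_from_session(stream: ImuStream,
                         filter_spec: FilterSpec = FilterSpec(),
                         spec: WindowSpec = WindowSpec(),
                         subject_id=None) -> WindowedDataset:
    """Convenience chain: filter, downsample, segment and label a raw
    labelled session stream."""
    conditioned = preprocess_stream(stream, filter_spec, spec.rate_hz)
    dataset = segment(conditioned, spec)
    if conditioned.labels is not None:
        dataset = label_windows(dataset, conditioned.labels, spec)
    if subject_id is not None:
        dataset.subject_ids = np.full(len(dataset), subject_id, dtype=object)
    return dataset
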