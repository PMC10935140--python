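"""Sliding-window segmentation and time-domain feature extraction.

Each harmonized recording is cut into 2 s windows with 50% overlap; every
window becomes one classification instance labeled by the majority of its
per-sample labels (ties go to the fall class, prioritizing sensitivity).
Thirteen summary statistics are computed on each of the six IMU channels,
yielding 78 features per window.

Feature definitions (fixed; degenerate zero-variance windows return 0 for
shape statistics):

====================  =====================================================
max / min             extreme amplitudes
zero_crossings        #{i : x_i * x_{i+1} < 0} on the raw signal
q1 / q3               linear-interpolation quartiles
std                   population standard deviation
mean / median         location
skewness              m3 / m2^{3/2}
energy                mean of squared values (mean signal power)
rms                   sqrt(mean of squares)  (so rms² == energy)
kurtosis              m4 / m2² (non-excess)
autocorr              lag-1 sample autocorrelation coefficient
====================  =====================================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .harmonize import CHANNELS, ImuRecording

#: feature order within each channel block (fixed, documented)
FEATURE_NAMES = ("max", "min", "zero_crossings", "q3", "std", "mean",
                 "median", "skewness", "energy", "rms", "q1", "kurtosis",
                 "autocorr")

#: the 78 feature columns, channel-major
FEATURE_COLUMNS = tuple(f"{ch}__{feat}"
                        for ch in CHANNELS for feat in FEATURE_NAMES)

METADATA_COLUMNS = ("dataset", "subject", "activity", "trial",
                    "window_index", "label")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window parameters: duration in seconds, overlap fraction."""

    duration: float = 2.0
    overlap: float = 0.5

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("window duration must be positive")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")

    def resolve(self, sample_rate: float) -> tuple[int, int]:
        """(window_len, stride) in samples at the given rate."""
        window_len = int(round(self.duration * sample_rate))
        stride = int(round(window_len * (1 - self.overlap)))
        if window_len < 1 or stride < 1:
            raise ValueError("window too short at this sample rate")
        return window_len, stride


def segment_windows(n_samples: int, window_len: int,
                    stride: int) -> list[tuple[int, int]]:
    """Half-open [start, start + window_len) index ranges at stride steps.

    A trailing partial window is discarded; streams shorter than one window
    yield no windows.
    """
    if n_samples < 0:
        raise ValueError("n_samples must be non-negative")
    if window_len < 1 or stride < 1:
        raise ValueError("window_len and stride must be >= 1")
    starts = range(0, n_samples - window_len + 1, stride)
    return [(s, s + window_len) for s in starts]


def majority_label(labels) -> int:
    """Modal label of a window; an exact tie resolves to 1 (fall)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("cannot label an empty window")
    ones = int(np.count_nonzero(labels))
    return 1 if ones * 2 >= labels.size else 0


# ---------------------------------------------------------------------------
# feature computation (vectorized over a stack of windows)
# ---------------------------------------------------------------------------

def _feature_table(windows: np.ndarray) -> dict[str, np.ndarray]:
    """All 13 features for a (n_windows, window_len) stack of signals."""
    w = np.asarray(windows, dtype=float)
    if w.ndim != 2 or w.shape[1] < 1:
        raise ValueError("windows must be a non-empty 2-D stack")
    mean = w.mean(axis=1)
    centered = w - mean[:, None]
    m2 = np.mean(centered ** 2, axis=1)
    m3 = np.mean(centered ** 3, axis=1)
    m4 = np.mean(centered ** 4, axis=1)
    nonzero = m2 > 0
    skew = np.zeros_like(m2)
    kurt = np.zeros_like(m2)
    with np.errstate(invalid="ignore", divide="ignore"):
        skew[nonzero] = m3[nonzero] / m2[nonzero] ** 1.5
        kurt[nonzero] = m4[nonzero] / m2[nonzero] ** 2
    # lag-1 autocorrelation: sum_{t<n-1} c_t c_{t+1} / sum_t c_t^2
    denom = (centered ** 2).sum(axis=1)
    num = (centered[:, :-1] * centered[:, 1:]).sum(axis=1) \
        if w.shape[1] > 1 else np.zeros_like(denom)
    autocorr = np.divide(num, denom, out=np.zeros_like(denom),
                         where=denom > 0)
    energy = np.mean(w ** 2, axis=1)
    return {
        "max": w.max(axis=1),
        "min": w.min(axis=1),
        "zero_crossings": np.count_nonzero(
            w[:, :-1] * w[:, 1:] < 0, axis=1).astype(float),
        "q3": np.quantile(w, 0.75, axis=1),
        "std": np.sqrt(m2),
        "mean": mean,
        "median": np.median(w, axis=1),
        "skewness": skew,
        "energy": energy,
        "rms": np.sqrt(energy),
        "q1": np.quantile(w, 0.25, axis=1),
        "kurtosis": kurt,
        "autocorr": autocorr,
    }


def compute_feature(name: str, window_values) -> float:
    """One named feature of a single window (scalar convenience path)."""
    if name not in FEATURE_NAMES:
        raise ValueError(f"unknown feature {name!r}; "
                         f"expected one of {list(FEATURE_NAMES)}")
    values = np.atleast_2d(np.asarray(window_values, dtype=float))
    return float(_feature_table(values)[name][0])


# ---------------------------------------------------------------------------
# extraction drivers
# ---------------------------------------------------------------------------

def extract_features(rec: ImuRecording,
                     spec: WindowSpec = WindowSpec()) -> pd.DataFrame:
    """One feature row per window of a recording.

    Columns: the six metadata columns first, then the 78 features in the
    fixed order of :data:`FEATURE_COLUMNS`.  A recording shorter than one
    window yields an empty frame with the full schema.
    """
    window_len, stride = spec.resolve(rec.sample_rate)
    bounds = segment_windows(rec.n_samples, window_len, stride)
    schema = list(METADATA_COLUMNS) + list(FEATURE_COLUMNS)
    if not bounds:
        return pd.DataFrame(columns=schema)
    starts = np.array([s for s, _ in bounds])
    idx = starts[:, None] + np.arange(window_len)[None, :]
    channels = rec.channels
    data: dict[str, np.ndarray] = {
        "dataset": np.repeat(rec.dataset, len(bounds)),
        "subject": np.repeat(rec.subject, len(bounds)),
        "activity": np.repeat(rec.activity, len(bounds)),
        "trial": np.repeat(rec.trial, len(bounds)),
        "window_index": np.arange(len(bounds)),
        "label": np.array([majority_label(rec.labels[s:e])
                           for s, e in bounds]),
    }
    for c, ch in enumerate(CHANNELS):
        table = _feature_table(channels[idx, c])
        for feat in FEATURE_NAMES:
            data[f"{ch}__{feat}"] = table[feat]
    return pd.DataFrame(data, columns=schema)


def extract_corpus_features(recordings: list[ImuRecording],
                            spec: WindowSpec = WindowSpec()) -> pd.DataFrame:
    """Concatenate per-recording feature rows into one corpus matrix."""
    frames = [extract_features(rec, spec) for rec in recordings]
    schema = list(METADATA_COLUMNS) + list(FEATURE_COLUMNS)
    frames = [f for f in frames if not f.empty]
    if not frames:
        return pd.DataFrame(columns=schema)
    return pd.concat(frames, ignore_index=True)


def acc_norm_peaks(rec: ImuRecording, spec: WindowSpec = WindowSpec(),
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-window peak acceleration norm (g) and majority labels.

    Input for the magnitude-threshold baseline detector; expects raw
    (unnormalized) acceleration in g.
    """
    window_len, stride = spec.resolve(rec.sample_rate)
    bounds = segment_windows(rec.n_samples, window_len, stride)
    norm = np.linalg.norm(rec.acc, axis=1)
    peaks = np.array([norm[s:e].max() for s, e in bounds])
    labels = np.array([majority_label(rec.labels[s:e]) for s, e in bounds])
    return peaks, labels
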