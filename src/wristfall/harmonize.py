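"""Standardize heterogeneous wrist-IMU sources into one uniform corpus.

Multi-source fall datasets arrive with different sampling rates (18/20/50 Hz
here), different raw units (g vs m/s², rad/s vs deg/s) and different file
layouts.  This module provides the harmonization steps that make them
commensurable: a filename codec (``<Dataset>_SubjectXX_ActivityXX_TrialXX``),
unit unification to g and rad/s, resampling onto a common 18 Hz grid,
whole-file removal of recordings containing non-finite values, and optional
min-max normalization of every channel to [-1, 1].

The canonical in-memory container is :class:`ImuRecording`: a uniform
time grid, triaxial accelerometer in g, triaxial gyroscope in rad/s, and a
per-sample binary label (0 = activity of daily living, 1 = fall).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: standard gravity, m/s² per g
GRAVITY = 9.80665

#: canonical target rate of the harmonized corpus, Hz (lowest source rate)
TARGET_RATE_HZ = 18.0

#: channel order used everywhere (normalization params, feature columns)
CHANNELS = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")

TRIAL_CSV_COLUMNS = ("time_s", "acc_x", "acc_y", "acc_z",
                     "gyr_x", "gyr_y", "gyr_z", "label")

MANIFEST_COLUMNS = ("dataset", "subject", "activity", "trial", "path",
                    "sample_rate_hz", "acc_units", "gyr_units",
                    "is_fall_activity")


class FilenameError(ValueError):
    """A trial filename does not follow the naming convention."""


@dataclass
class ImuRecording:
    """One trial: a 6-channel IMU stream on a uniform grid with labels.

    ``acc`` is (n, 3) in g, ``gyr`` is (n, 3) in rad/s, ``labels`` is (n,)
    with values in {0, 1}.  ``time`` is seconds, strictly increasing and
    uniform at ``sample_rate``.
    """

    dataset: str
    subject: int
    activity: int
    trial: int
    sample_rate: float
    time: np.ndarray
    acc: np.ndarray
    gyr: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyr = np.asarray(self.gyr, dtype=float)
        self.labels = np.asarray(self.labels)
        n = self.time.shape[0]
        if self.acc.shape != (n, 3) or self.gyr.shape != (n, 3):
            raise ValueError("acc and gyr must be (n, 3) arrays matching time")
        if self.labels.shape != (n,):
            raise ValueError("labels must match the number of samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if n >= 2:
            dt = np.diff(self.time)
            period = 1.0 / self.sample_rate
            if np.any(dt <= 0) or np.any(np.abs(dt - period) > period):
                raise ValueError("time must be strictly increasing and "
                                 "uniform at sample_rate")

    @property
    def n_samples(self) -> int:
        return self.time.shape[0]

    @property
    def channels(self) -> np.ndarray:
        """(n, 6) view in the canonical channel order."""
        return np.column_stack([self.acc, self.gyr])

    def with_channels(self, channels: np.ndarray) -> "ImuRecording":
        channels = np.asarray(channels, dtype=float)
        return replace(self, acc=channels[:, :3], gyr=channels[:, 3:])

    @property
    def subject_key(self) -> tuple[str, int]:
        """Dataset-qualified subject identity used for grouped CV."""
        return (self.dataset, self.subject)


# ---------------------------------------------------------------------------
# filename codec
# ---------------------------------------------------------------------------

_FILENAME_RE = re.compile(
    r"^(?P<dataset>.+)_Subject(?P<subject>\d{2})"
    r"_Activity(?P<activity>\d{2})_Trial(?P<trial>\d{2})$"
)


def format_filename(dataset: str, subject: int, activity: int,
                    trial: int) -> str:
    """Render the ``<Dataset>_SubjectXX_ActivityXX_TrialXX`` stem."""
    if not dataset:
        raise FilenameError("dataset name must be non-empty")
    return (f"{dataset}_Subject{subject:02d}"
            f"_Activity{activity:02d}_Trial{trial:02d}")


def parse_filename(name: str) -> tuple[str, int, int, int]:
    """Parse a trial file stem into (dataset, subject, activity, trial).

    Accepts an optional ``.csv`` extension.  Raises :class:`FilenameError`
    naming the first offending token on malformed input.
    """
    stem = name[:-4] if name.endswith(".csv") else name
    m = _FILENAME_RE.match(stem)
    if m is None:
        for token in ("Trial", "Activity", "Subject"):
            if not re.search(rf"_{token}\d{{2}}", stem):
                raise FilenameError(
                    f"cannot parse {name!r}: missing or malformed "
                    f"'{token}XX' token")
        raise FilenameError(f"cannot parse {name!r}: bad dataset prefix")
    return (m["dataset"], int(m["subject"]),
            int(m["activity"]), int(m["trial"]))


# ---------------------------------------------------------------------------
# unit unification
# ---------------------------------------------------------------------------

_ACC_UNITS = {"g": 1.0, "m/s2": 1.0 / GRAVITY, "m/s^2": 1.0 / GRAVITY,
              "m/s²": 1.0 / GRAVITY}
_GYR_UNITS = {"rad/s": 1.0, "deg/s": np.pi / 180.0}


def convert_units(values, quantity: str, from_units: str) -> np.ndarray:
    """Convert raw sensor values to canonical units (g or rad/s).

    ``quantity`` is ``"acceleration"`` (accepted inputs: g, m/s²) or
    ``"angular_velocity"`` (rad/s, deg/s).  Conversion is the identity when
    the input already is canonical.
    """
    values = np.asarray(values, dtype=float)
    if quantity == "acceleration":
        table = _ACC_UNITS
    elif quantity == "angular_velocity":
        table = _GYR_UNITS
    else:
        raise ValueError(f"unknown quantity {quantity!r}")
    try:
        factor = table[from_units]
    except KeyError:
        raise ValueError(
            f"unknown {quantity} unit {from_units!r}; "
            f"expected one of {sorted(table)}") from None
    return values * factor


def convert_units_back(values, quantity: str, to_units: str) -> np.ndarray:
    """Inverse of :func:`convert_units` (canonical -> declared units)."""
    one = convert_units(np.array(1.0), quantity, to_units)
    return np.asarray(values, dtype=float) / float(one)


# ---------------------------------------------------------------------------
# trial / manifest I/O
# ---------------------------------------------------------------------------

def write_trial_csv(rec: ImuRecording, path: Path | str,
                    acc_units: str = "g", gyr_units: str = "rad/s") -> None:
    """Write one trial CSV in the declared raw units of its source."""
    acc = convert_units_back(rec.acc, "acceleration", acc_units)
    gyr = convert_units_back(rec.gyr, "angular_velocity", gyr_units)
    df = pd.DataFrame({
        "time_s": rec.time,
        "acc_x": acc[:, 0], "acc_y": acc[:, 1], "acc_z": acc[:, 2],
        "gyr_x": gyr[:, 0], "gyr_y": gyr[:, 1], "gyr_z": gyr[:, 2],
        "label": rec.labels.astype(int),
    })
    df.to_csv(path, index=False, float_format="%.6f")


def read_trial_csv(path: Path | str, *, dataset: str, subject: int,
                   activity: int, trial: int, sample_rate: float,
                   acc_units: str = "g",
                   gyr_units: str = "rad/s") -> ImuRecording:
    """Read a trial CSV and convert it into canonical units (g, rad/s)."""
    df = pd.read_csv(path)
    missing = set(TRIAL_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing trial columns {sorted(missing)}")
    acc = convert_units(df[["acc_x", "acc_y", "acc_z"]].to_numpy(),
                        "acceleration", acc_units)
    gyr = convert_units(df[["gyr_x", "gyr_y", "gyr_z"]].to_numpy(),
                        "angular_velocity", gyr_units)
    return ImuRecording(dataset=dataset, subject=subject, activity=activity,
                        trial=trial, sample_rate=sample_rate,
                        time=df["time_s"].to_numpy(), acc=acc, gyr=gyr,
                        labels=df["label"].to_numpy())


def load_recording(row: pd.Series, base_dir: Path | str) -> ImuRecording:
    """Load the recording a manifest row points at, in canonical units."""
    return read_trial_csv(
        Path(base_dir) / row["path"],
        dataset=row["dataset"], subject=int(row["subject"]),
        activity=int(row["activity"]), trial=int(row["trial"]),
        sample_rate=float(row["sample_rate_hz"]),
        acc_units=row["acc_units"], gyr_units=row["gyr_units"])


def validate_manifest(manifest: pd.DataFrame) -> None:
    missing = set(MANIFEST_COLUMNS[:8]) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    keys = manifest[["dataset", "subject", "activity", "trial"]]
    if keys.duplicated().any():
        raise ValueError("manifest has duplicate "
                         "(dataset, subject, activity, trial) keys")


def read_manifest(path: Path | str) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    validate_manifest(manifest)
    return manifest


def write_manifest(manifest: pd.DataFrame, path: Path | str) -> None:
    validate_manifest(manifest)
    manifest.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample_recording(rec: ImuRecording,
                       target_rate: float = TARGET_RATE_HZ) -> ImuRecording:
    """Resample onto a uniform grid at ``target_rate``.

    Channel values are linearly interpolated at the new grid times; labels
    (categorical) are taken from the nearest original sample.  The output
    grid spans [t0, t_end] with floor((t_end - t0) * target_rate) + 1
    samples.  A recording already at the target rate (within 1e-9 relative)
    is returned as a copy.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if rec.n_samples < 2:
        raise ValueError("need at least 2 samples to resample")
    if abs(rec.sample_rate - target_rate) <= 1e-9 * target_rate:
        return replace(rec)
    t0, t_end = rec.time[0], rec.time[-1]
    n_out = int(np.floor((t_end - t0) * target_rate + 1e-9)) + 1
    new_time = t0 + np.arange(n_out) / target_rate
    channels = rec.channels
    new_channels = np.column_stack(
        [np.interp(new_time, rec.time, channels[:, c]) for c in range(6)])
    nearest = np.clip(
        np.round((new_time - t0) * rec.sample_rate).astype(int),
        0, rec.n_samples - 1)
    return ImuRecording(
        dataset=rec.dataset, subject=rec.subject, activity=rec.activity,
        trial=rec.trial, sample_rate=target_rate, time=new_time,
        acc=new_channels[:, :3], gyr=new_channels[:, 3:],
        labels=rec.labels[nearest])


# ---------------------------------------------------------------------------
# NaN-file removal
# ---------------------------------------------------------------------------

def drop_invalid(manifest: pd.DataFrame,
                 base_dir: Path | str) -> pd.DataFrame:
    """Drop every trial whose file contains any non-finite or missing value.

    Whole files are removed, not rows; a log line records each removal.
    A missing file is likewise removed with a warning.
    """
    base_dir = Path(base_dir)
    keep = []
    for idx, row in manifest.iterrows():
        path = base_dir / row["path"]
        if not path.exists():
            logger.warning("dropping %s: file not found", row["path"])
            continue
        df = pd.read_csv(path)
        values = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            logger.warning("dropping %s: non-finite values present",
                           row["path"])
            continue
        keep.append(idx)
    return manifest.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# [-1, 1] normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationParams:
    """Fitted per-channel min/max ranges, keyed by scope.

    Scope keys are dataset names in ``per_dataset`` mode and the single key
    ``"__global__"`` otherwise.  Each entry maps to (min, max) arrays of
    length 6 in the canonical channel order.
    """

    mode: str
    ranges: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict)

    def to_json(self, path: Path | str) -> None:
        payload = {
            "mode": self.mode,
            "channels": list(CHANNELS),
            "ranges": {k: {"min": lo.tolist(), "max": hi.tolist()}
                       for k, (lo, hi) in self.ranges.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: Path | str) -> "NormalizationParams":
        payload = json.loads(Path(path).read_text())
        ranges = {k: (np.asarray(v["min"], float), np.asarray(v["max"], float))
                  for k, v in payload["ranges"].items()}
        return cls(mode=payload["mode"], ranges=ranges)


NORMALIZATION_MODES = ("off", "per_dataset", "fit_on_train")


def fit_normalization(recordings: list[ImuRecording], mode: str,
                      ) -> NormalizationParams:
    """Fit per-channel min/max over the given recordings.

    ``per_dataset`` fits one range per dataset name (mirroring whole-corpus
    normalization before splitting); ``fit_on_train`` fits a single global
    range, intended to be fitted on the training partition only.
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if not recordings:
        raise ValueError("need at least one recording to fit normalization")
    params = NormalizationParams(mode=mode)
    if mode == "off":
        return params

    def _fit(recs: list[ImuRecording]) -> tuple[np.ndarray, np.ndarray]:
        stacked = np.vstack([r.channels for r in recs])
        return stacked.min(axis=0), stacked.max(axis=0)

    if mode == "per_dataset":
        datasets: dict[str, list[ImuRecording]] = {}
        for rec in recordings:
            datasets.setdefault(rec.dataset, []).append(rec)
        for name, recs in datasets.items():
            params.ranges[name] = _fit(recs)
    else:  # fit_on_train
        params.ranges["__global__"] = _fit(recordings)
    return params


def apply_normalization(recordings: list[ImuRecording],
                        params: NormalizationParams) -> list[ImuRecording]:
    """Map each channel affinely so the fitted min -> -1 and max -> +1.

    Constant channels (max == min) map to 0.  In ``fit_on_train`` mode the
    single global range is applied to every recording, including datasets
    unseen at fit time.
    """
    if params.mode == "off":
        return [replace(r) for r in recordings]
    out = []
    for rec in recordings:
        key = rec.dataset if params.mode == "per_dataset" else "__global__"
        if key not in params.ranges:
            raise KeyError(f"no fitted range for scope {key!r}")
        lo, hi = params.ranges[key]
        span = hi - lo
        channels = rec.channels
        scaled = np.zeros_like(channels)
        nz = span > 0
        scaled[:, nz] = 2.0 * (channels[:, nz] - lo[nz]) / span[nz] - 1.0
        out.append(rec.with_channels(scaled))
    return out


def normalize_dataset(recordings: list[ImuRecording], mode: str = "off",
                      fit_recordings: list[ImuRecording] | None = None,
                      ) -> tuple[list[ImuRecording], NormalizationParams]:
    """Fit (on ``fit_recordings`` or all) and apply [-1, 1] normalization."""
    params = fit_normalization(
        fit_recordings if fit_recordings is not None else recordings, mode)
    return apply_normalization(recordings, params), params


# ---------------------------------------------------------------------------
# corpus driver
# ---------------------------------------------------------------------------

def harmonize_corpus(manifest: pd.DataFrame, base_dir: Path | str,
                     target_rate: float = TARGET_RATE_HZ,
                     normalization: str = "off",
                     ) -> tuple[list[ImuRecording], NormalizationParams]:
    """Full harmonization: drop invalid files, load into canonical units,
    resample to the common rate, and optionally normalize to [-1, 1]."""
    manifest = drop_invalid(manifest, base_dir)
    recordings = [resample_recording(load_recording(row, base_dir),
                                     target_rate)
                  for _, row in manifest.iterrows()]
    return normalize_dataset(recordings, mode=normalization)
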