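"""Core data containers, on-disk dataset format, and shared signal utilities.

One observation unit is a *snippet*: a 5 s synchronized recording of an
infant lying supine, captured by three sensor modalities —

* 2D pose key points extracted from video (50 Hz, 250 frames, 15 points),
* a 32x32 pressure-sensing mat (100 Hz, 500 frames),
* six 6-channel inertial measurement units (60 Hz, 300 frames).

Each snippet carries a human label: fidgety movements present (FM+, 1),
absent (FM-, 0), or not assessable (NA, excluded before classification).

Datasets are stored as a directory with a JSON manifest plus one ``.npy``
array per snippet per modality; the round trip is bit-exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "FM_MINUS", "FM_PLUS", "LABEL_NA", "SESSIONS",
    "KEYPOINT_NAMES", "HIP_INDICES", "SHOULDER_INDICES",
    "IMU_SENSOR_ORDER", "IMU_CHANNEL_ORDER",
    "VID", "MAT", "IMU", "FUSED", "MODALITIES",
    "SnippetMeta", "KeypointSnippet", "PressureSnippet", "IMUSnippet",
    "SnippetTriple", "Dataset", "FeatureMatrix", "NormStats",
    "read_dataset", "write_dataset", "filter_synchronized",
    "smooth_series", "fit_norm_stats", "apply_norm",
]

# Class labels: FM- = 0, FM+ = 1 throughout; NA marks not-assessable snippets.
FM_MINUS = 0
FM_PLUS = 1
LABEL_NA = -1
_LABEL_STR = {FM_MINUS: "FM-", FM_PLUS: "FM+", LABEL_NA: "NA"}
_STR_LABEL = {v: k for k, v in _LABEL_STR.items()}

SESSIONS = ("T1", "T2", "T3", "T4", "T5", "T6", "T7")

# 15-point skeleton: the 17 COCO points minus the two ears (three head
# points suffice for head position and orientation).
KEYPOINT_NAMES = (
    "nose", "left_eye", "right_eye",
    "left_shoulder", "right_shoulder",
    "left_elbow", "right_elbow",
    "left_wrist", "right_wrist",
    "left_hip", "right_hip",
    "left_knee", "right_knee",
    "left_ankle", "right_ankle",
)
SHOULDER_INDICES = (3, 4)
HIP_INDICES = (9, 10)

IMU_SENSOR_ORDER = (
    "left_shoulder", "right_shoulder",
    "left_hip", "right_hip",
    "left_foot", "right_foot",
)
IMU_CHANNEL_ORDER = ("ax", "ay", "az", "gx", "gy", "gz")

VID = "VID"
MAT = "MAT"
IMU = "IMU"
FUSED = "FUSED"
MODALITIES = (VID, MAT, IMU)

DURATION_S = 5.0
VID_RATE = 50.0
MAT_RATE = 100.0
IMU_RATE = 60.0
VID_FRAMES = 250
MAT_FRAMES = 500
IMU_FRAMES = 300


class ValidationError(ValueError):
    """Raised when a container violates a structural invariant."""


class DegenerateDataError(ValueError):
    """Raised when data is too degenerate for an operation (e.g. zero variance)."""


@dataclass(frozen=True)
class SnippetMeta:
    snippet_id: str
    infant_id: str
    session: str = "T5"
    label: int = LABEL_NA
    duration_s: float = DURATION_S

    def __post_init__(self):
        if self.session not in SESSIONS:
            raise ValidationError(f"unknown session {self.session!r} for {self.snippet_id}")
        if self.label not in (FM_MINUS, FM_PLUS, LABEL_NA):
            raise ValidationError(f"unknown label {self.label!r} for {self.snippet_id}")
        if self.duration_s != DURATION_S:
            raise ValidationError(f"snippet duration must be {DURATION_S} s")

    @property
    def label_str(self) -> str:
        return _LABEL_STR[self.label]


def _check_shape(values, expected, meta, modality):
    values = np.asarray(values)
    if values.shape != expected:
        raise ValidationError(
            f"{modality} array for snippet {meta.snippet_id!r} has shape "
            f"{values.shape}, expected {expected}"
        )
    if not np.all(np.isfinite(values)):
        raise ValidationError(
            f"{modality} array for snippet {meta.snippet_id!r} contains non-finite values"
        )
    return values


@dataclass(frozen=True)
class KeypointSnippet:
    """Pose key points, frames x 15 points x 2 (x, y) in pixel units.

    Coordinates use the mathematical convention (y up); the processing
    pipeline is invariant to this choice after centering/rotation/scaling.
    """

    values: np.ndarray
    meta: SnippetMeta
    frame_rate: float = VID_RATE
    keypoint_names: tuple = KEYPOINT_NAMES

    def __post_init__(self):
        object.__setattr__(
            self, "values",
            _check_shape(self.values, (VID_FRAMES, 15, 2), self.meta, "keypoints"),
        )

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class PressureSnippet:
    """Pressure-mat frames, frames x 32 x 32, non-negative sensor units."""

    values: np.ndarray
    meta: SnippetMeta
    frame_rate: float = MAT_RATE

    def __post_init__(self):
        values = _check_shape(self.values, (MAT_FRAMES, 32, 32), self.meta, "pressure")
        if np.any(values < 0):
            raise ValidationError(
                f"pressure array for snippet {self.meta.snippet_id!r} has negative values"
            )
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class IMUSnippet:
    """IMU streams, frames x 6 sensors x 6 channels (ax ay az gx gy gz)."""

    values: np.ndarray
    meta: SnippetMeta
    frame_rate: float = IMU_RATE
    sensor_order: tuple = IMU_SENSOR_ORDER
    channel_order: tuple = IMU_CHANNEL_ORDER

    def __post_init__(self):
        object.__setattr__(
            self, "values",
            _check_shape(self.values, (IMU_FRAMES, 6, 6), self.meta, "imu"),
        )


@dataclass(frozen=True)
class SnippetTriple:
    """One synchronized observation; absent modalities are None."""

    meta: SnippetMeta
    keypoints: KeypointSnippet | None = None
    pressure: PressureSnippet | None = None
    imu: IMUSnippet | None = None

    def __post_init__(self):
        for sub in (self.keypoints, self.pressure, self.imu):
            if sub is not None and sub.meta != self.meta:
                raise ValidationError(
                    f"sub-snippet metadata mismatch in {self.meta.snippet_id!r}"
                )

    def has(self, modality: str) -> bool:
        return {
            VID: self.keypoints,
            MAT: self.pressure,
            IMU: self.imu,
        }[modality] is not None

    @property
    def present_modalities(self) -> frozenset:
        return frozenset(m for m in MODALITIES if self.has(m))


@dataclass(frozen=True)
class Dataset:
    triples: tuple

    def __post_init__(self):
        object.__setattr__(self, "triples", tuple(self.triples))
        ids = [t.meta.snippet_id for t in self.triples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate snippet_id in dataset")

    def __len__(self) -> int:
        return len(self.triples)

    def __iter__(self):
        return iter(self.triples)

    @property
    def infant_ids(self) -> tuple:
        seen = []
        for t in self.triples:
            if t.meta.infant_id not in seen:
                seen.append(t.meta.infant_id)
        return tuple(seen)

    @property
    def labels(self) -> np.ndarray:
        return np.array([t.meta.label for t in self.triples], dtype=int)


@dataclass(frozen=True)
class FeatureMatrix:
    """A frames x channels feature matrix for one snippet and one modality."""

    values: np.ndarray
    modality: str
    channel_names: tuple
    meta: SnippetMeta

    _EXPECTED = {VID: None, MAT: None, IMU: None, FUSED: None}

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValidationError("feature matrix must be 2-D (frames x channels)")
        if values.shape[1] != len(self.channel_names):
            raise ValidationError(
                f"{values.shape[1]} columns but {len(self.channel_names)} channel names"
            )
        if not np.all(np.isfinite(values)):
            raise ValidationError(
                f"feature matrix for {self.meta.snippet_id!r} has non-finite entries"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# Pooled z-score normalization statistics
# ---------------------------------------------------------------------------

NORM_GROUPS = ("position", "velocity", "acceleration", "angular_velocity")


@dataclass(frozen=True)
class NormStats:
    """Pooled (mean, sd) per channel group, fitted on training data only.

    The pool for a group is the concatenation of every sample of every
    series assigned to that group across all training snippets, key
    points/sensors and coordinate axes. SD is the population standard
    deviation (divide by N).
    """

    stats: dict
    fitted_on: str = ""

    def __post_init__(self):
        for group, (mean, sd) in self.stats.items():
            if not sd > 0:
                raise DegenerateDataError(f"group {group!r} has non-positive sd {sd}")

    def __contains__(self, group: str) -> bool:
        return group in self.stats

    def mean(self, group: str) -> float:
        return self.stats[group][0]

    def sd(self, group: str) -> float:
        return self.stats[group][1]

    def to_dict(self) -> dict:
        return {
            "fitted_on": self.fitted_on,
            "stats": {g: [float(m), float(s)] for g, (m, s) in self.stats.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormStats":
        return cls(
            stats={g: (float(m), float(s)) for g, (m, s) in d["stats"].items()},
            fitted_on=d.get("fitted_on", ""),
        )


def fit_norm_stats(feature_series: dict, fitted_on: str = "") -> NormStats:
    """Fit pooled (mean, sd) per group from ``{group: [1-D or n-D arrays]}``.

    All values of all arrays in a group are pooled into one sample; the
    population SD convention (ddof=0) is used. A group with zero pooled
    variance raises :class:`DegenerateDataError`.
    """
    stats = {}
    for group, series_list in feature_series.items():
        if not series_list:
            raise ValueError(f"group {group!r} has no series")
        pool = np.concatenate([np.asarray(s, dtype=float).ravel() for s in series_list])
        mean = float(pool.mean())
        sd = float(pool.std(ddof=0))
        if not sd > 0:
            raise DegenerateDataError(f"zero pooled variance in group {group!r}")
        stats[group] = (mean, sd)
    return NormStats(stats=stats, fitted_on=fitted_on)


def apply_norm(values: np.ndarray, group: str, stats: NormStats) -> np.ndarray:
    """Elementwise ``(x - mean) / sd`` with the training-set stats of *group*."""
    if group not in stats:
        raise KeyError(f"NormStats has no group {group!r}")
    return (np.asarray(values, dtype=float) - stats.mean(group)) / stats.sd(group)


# ---------------------------------------------------------------------------
# Smoothing filters
# ---------------------------------------------------------------------------

def _check_window(window: int, n: int) -> int:
    window = int(window)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if window > n:
        raise ValueError(f"window {window} longer than series of length {n}")
    return window


def smooth_series(series: np.ndarray, window: int, kind: str = "moving_average") -> np.ndarray:
    """Centered sliding-window filter (median or moving average).

    Boundary frames use the truncated window that fits inside the series,
    so the output has the same length as the input and no data is invented
    at the edges.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("smooth_series expects a 1-D array")
    if kind == "moving_average":
        return _moving_average_columns(x[:, None], window)[:, 0]
    if kind == "median":
        return _median_columns(x[:, None], window)[:, 0]
    raise ValueError(f"unknown filter kind {kind!r}")


def _moving_average_columns(x: np.ndarray, window: int) -> np.ndarray:
    """Truncated-window centered moving average applied to each column."""
    n = x.shape[0]
    window = _check_window(window, n)
    if window == 1:
        return x.copy()
    h = window // 2
    csum = np.concatenate([np.zeros((1, x.shape[1])), np.cumsum(x, axis=0)])
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h, n - 1)
    out = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)[:, None]
    return out


def _median_columns(x: np.ndarray, window: int) -> np.ndarray:
    """Truncated-window centered running median applied to each column."""
    n = x.shape[0]
    window = _check_window(window, n)
    if window == 1:
        return x.copy()
    h = window // 2
    out = np.empty_like(x)
    interior = np.lib.stride_tricks.sliding_window_view(x, window, axis=0)
    out[h:n - h] = np.median(interior, axis=-1)
    for i in range(h):                      # truncated windows at both edges
        out[i] = np.median(x[: i + h + 1], axis=0)
        out[n - 1 - i] = np.median(x[n - 1 - i - h:], axis=0)
    return out


# ---------------------------------------------------------------------------
# Dataset I/O and synchronization filtering
# ---------------------------------------------------------------------------

_MODALITY_KEYS = {"keypoints": VID, "pressure": MAT, "imu": IMU}


def write_dataset(dataset: Dataset, out_dir) -> Path:
    """Write *dataset* to *out_dir* (JSON manifest + one .npy per modality).

    Returns the manifest path. ``read_dataset`` on the result reproduces
    the dataset bit-exactly.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        arrays_dir = out_dir / "arrays"
        arrays_dir.mkdir(exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create dataset directory {out_dir}: {exc}") from exc

    rows = []
    for triple in dataset:
        meta = triple.meta
        row = {
            "snippet_id": meta.snippet_id,
            "infant_id": meta.infant_id,
            "session": meta.session,
            "label": meta.label_str,
        }
        for key, snip in (
            ("keypoints", triple.keypoints),
            ("pressure", triple.pressure),
            ("imu", triple.imu),
        ):
            if snip is None:
                row[key] = "none"
            else:
                rel = f"arrays/{meta.snippet_id}_{key}.npy"
                np.save(out_dir / rel, snip.values)
                row[key] = rel
        rows.append(row)

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(rows, indent=1))
    return manifest_path


def read_dataset(manifest_path) -> Dataset:
    """Read a dataset written by :func:`write_dataset`."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise OSError(f"manifest not found: {manifest_path}")
    base = manifest_path.parent
    rows = json.loads(manifest_path.read_text())

    triples = []
    for row in rows:
        label = row["label"]
        if label not in _STR_LABEL:
            raise ValidationError(
                f"unknown label {label!r} for snippet {row.get('snippet_id')!r}"
            )
        meta = SnippetMeta(
            snippet_id=row["snippet_id"],
            infant_id=row["infant_id"],
            session=row["session"],
            label=_STR_LABEL[label],
        )
        parts = {}
        for key, cls in (
            ("keypoints", KeypointSnippet),
            ("pressure", PressureSnippet),
            ("imu", IMUSnippet),
        ):
            rel = row[key]
            if rel == "none":
                parts[key] = None
                continue
            path = base / rel
            if not path.exists():
                raise OSError(f"array file missing for snippet {meta.snippet_id!r}: {path}")
            parts[key] = cls(values=np.load(path), meta=meta)
        triples.append(SnippetTriple(meta=meta, **parts))
    return Dataset(triples=tuple(triples))


def filter_synchronized(dataset: Dataset, required=frozenset(MODALITIES)) -> Dataset:
    """Keep triples that carry every required modality and a usable label.

    Mirrors the study's exclusion of snippets without synchronized
    pressure/IMU data and of snippets labeled not-assessable. Order is
    preserved; the operation is idempotent.
    """
    required = frozenset(required)
    kept = tuple(
        t for t in dataset
        if t.meta.label != LABEL_NA and required <= t.present_modalities
    )
    return Dataset(triples=kept)
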