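"""IMU feature extraction: six 6-channel sensors -> 300 x 36 matrix.

Each of the 36 channel series (sensor-major: ax ay az gx gy gz for sensor
1, then sensor 2, ...) is smoothed with a moving-average filter (window
5) and mean-centered per series — which removes, among other offsets, the
constant gravity component on the accelerometer channels. Acceleration
and angular-velocity channels are then z-scored separately with pooled
training-set statistics, making the pipeline agnostic to the physical
units of either channel family.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .snippets import (
    IMU,
    IMU_CHANNEL_ORDER,
    IMU_SENSOR_ORDER,
    FeatureMatrix,
    IMUSnippet,
    NormStats,
    _moving_average_columns,
    apply_norm,
    fit_norm_stats,
)

__all__ = [
    "build_imu_features", "IMUFeatureExtractor", "imu_channel_names",
    "ACCEL_COLUMNS", "GYRO_COLUMNS",
]

_SMOOTH_WINDOW = 5

# Column masks over the 36 sensor-major channels: per sensor the first
# three channels are the accelerometer triplet, the last three the gyro.
ACCEL_COLUMNS = np.array([c % 6 < 3 for c in range(36)])
GYRO_COLUMNS = ~ACCEL_COLUMNS


def imu_channel_names() -> tuple:
    return tuple(
        f"{sensor}_{channel}"
        for sensor in IMU_SENSOR_ORDER
        for channel in IMU_CHANNEL_ORDER
    )


def _smoothed_centered(snippet: IMUSnippet) -> np.ndarray:
    """(300, 36) matrix after smoothing and per-series mean centering."""
    n = snippet.values.shape[0]
    flat = snippet.values.reshape(n, 36)
    flat = _moving_average_columns(flat, _SMOOTH_WINDOW)
    return flat - flat.mean(axis=0, keepdims=True)


def build_imu_features(snippet: IMUSnippet, stats: NormStats) -> FeatureMatrix:
    """Normalized 300 x 36 IMU feature matrix.

    Requires ``acceleration`` and ``angular_velocity`` groups in *stats*
    (fitted on training data); the two channel families are normalized
    independently.
    """
    for g in ("acceleration", "angular_velocity"):
        if g not in stats:
            raise KeyError(f"NormStats is missing required group {g!r}")
    centered = _smoothed_centered(snippet)
    out = np.empty_like(centered)
    out[:, ACCEL_COLUMNS] = apply_norm(centered[:, ACCEL_COLUMNS], "acceleration", stats)
    out[:, GYRO_COLUMNS] = apply_norm(centered[:, GYRO_COLUMNS], "angular_velocity", stats)
    return FeatureMatrix(
        values=out,
        modality=IMU,
        channel_names=imu_channel_names(),
        meta=snippet.meta,
    )


class IMUFeatureExtractor(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: IMU snippets -> (n, 300, 36) features.

    ``fit`` pools the smoothed, per-series-centered acceleration channels
    (and, separately, the gyro channels) of the training snippets into one
    sample each and stores the resulting z-score statistics.
    """

    def fit(self, snippets, y=None):
        pools = {"acceleration": [], "angular_velocity": []}
        for snip in snippets:
            centered = _smoothed_centered(snip)
            pools["acceleration"].append(centered[:, ACCEL_COLUMNS])
            pools["angular_velocity"].append(centered[:, GYRO_COLUMNS])
        self.norm_stats_ = fit_norm_stats(pools, fitted_on="imu-training-pool")
        return self

    def transform_snippet(self, snippet: IMUSnippet) -> FeatureMatrix:
        return build_imu_features(snippet, self.norm_stats_)

    def transform(self, snippets) -> np.ndarray:
        return np.stack([self.transform_snippet(s).values for s in snippets])
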