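"""Skeleton key-point preprocessing and the 250 x 60 video feature matrix.

The chain follows the standard skeleton-normalization recipe for supine
infants: outlier removal/smoothing (median then moving-average filter,
window 5), centering on the time-averaged hip midpoint, rotating the
trunk midline onto the +Y axis, scaling the hip-shoulder distance to 1/3,
per-series mean centering, finite-difference velocities, and pooled
z-score normalization of positions and velocities with training-set
statistics. The result is a 250-frame x 60-column matrix (30 position
columns followed by 30 velocity columns, x/y interleaved per key point).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .snippets import (
    HIP_INDICES,
    KEYPOINT_NAMES,
    SHOULDER_INDICES,
    VID,
    DegenerateDataError,
    FeatureMatrix,
    KeypointSnippet,
    NormStats,
    _median_columns,
    _moving_average_columns,
    apply_norm,
    fit_norm_stats,
)

__all__ = [
    "clean_trajectories", "center_skeleton", "rotate_skeleton", "scale_skeleton",
    "preprocess_keypoints", "keypoint_velocity", "build_video_features",
    "VideoFeatureExtractor", "video_channel_names",
]

_FILTER_WINDOW = 5


def _with_values(snippet: KeypointSnippet, values: np.ndarray) -> KeypointSnippet:
    return KeypointSnippet(values=values, meta=snippet.meta,
                           frame_rate=snippet.frame_rate,
                           keypoint_names=snippet.keypoint_names)


def clean_trajectories(snippet: KeypointSnippet) -> KeypointSnippet:
    """Median filter then moving-average filter (window 5) per coordinate series.

    The median pass removes isolated pose-estimation outliers; the
    moving-average pass smooths jitter. There is no separate outlier
    detection step.
    """
    n = snippet.values.shape[0]
    flat = snippet.values.reshape(n, -1)
    flat = _median_columns(flat, _FILTER_WINDOW)
    flat = _moving_average_columns(flat, _FILTER_WINDOW)
    return _with_values(snippet, flat.reshape(snippet.values.shape))


def hip_center(values: np.ndarray) -> np.ndarray:
    """Across-frames average midpoint of the two hip key points."""
    hips = values[:, HIP_INDICES, :]          # (frames, 2, 2)
    return hips.mean(axis=(0, 1))


def shoulder_center(values: np.ndarray) -> np.ndarray:
    """Across-frames average midpoint of the two shoulder key points."""
    shoulders = values[:, SHOULDER_INDICES, :]
    return shoulders.mean(axis=(0, 1))


def center_skeleton(snippet: KeypointSnippet) -> KeypointSnippet:
    """Subtract the time-averaged hip midpoint from every key point."""
    hc = hip_center(snippet.values)
    return _with_values(snippet, snippet.values - hc)


def rotate_skeleton(snippet: KeypointSnippet) -> KeypointSnippet:
    """Rotate so the hip-to-shoulder midline lands on the positive Y axis.

    The rotation angle is the signed angle ``atan2(sc_x, sc_y)`` of the
    time-averaged shoulder midpoint (the skeleton is already hip-centered),
    so left- and right-tilted skeletons both align onto +Y; an unsigned
    acos would mirror one tilt direction.
    """
    sc = shoulder_center(snippet.values)
    norm = float(np.hypot(sc[0], sc[1]))
    if norm <= 1e-12:
        raise DegenerateDataError(
            f"shoulder center coincides with hip center in {snippet.meta.snippet_id!r}"
        )
    alpha = np.arctan2(sc[0], sc[1])
    c, s = np.cos(alpha), np.sin(alpha)
    rot = np.array([[c, -s], [s, c]])
    rotated = snippet.values @ rot.T
    return _with_values(snippet, rotated)


def scale_skeleton(snippet: KeypointSnippet) -> KeypointSnippet:
    """Scale so the hip-to-shoulder trunk length equals 1/3.

    Divides all coordinates by ``3 * |hc_y - sc_y|`` (the skeleton is
    centered and rotated, so trunk length is purely vertical).
    """
    hc = hip_center(snippet.values)
    sc = shoulder_center(snippet.values)
    trunk = abs(float(hc[1] - sc[1]))
    if trunk <= 1e-12:
        raise DegenerateDataError(
            f"zero trunk length in snippet {snippet.meta.snippet_id!r}"
        )
    return _with_values(snippet, snippet.values / (3.0 * trunk))


def preprocess_keypoints(snippet: KeypointSnippet) -> np.ndarray:
    """Full geometric chain; returns (frames, 15, 2) mean-centered coordinates.

    clean -> center -> rotate -> scale -> per-series mean centering. After
    this the coordinates are dimensionless and every coordinate series has
    zero mean over frames.
    """
    s = scale_skeleton(rotate_skeleton(center_skeleton(clean_trajectories(snippet))))
    values = s.values - s.values.mean(axis=0, keepdims=True)
    return values


def keypoint_velocity(positions: np.ndarray) -> np.ndarray:
    """Central-difference velocity per frame (forward/backward at the edges).

    Units are (dimensionless position)/frame; the constant frame-rate
    factor is absorbed by the downstream z-scoring.
    """
    v = np.empty_like(positions)
    v[1:-1] = (positions[2:] - positions[:-2]) / 2.0
    v[0] = positions[1] - positions[0]
    v[-1] = positions[-1] - positions[-2]
    return v


def video_channel_names(include_acceleration: bool = False) -> tuple:
    names = []
    for tag in ("p", "v") + (("a",) if include_acceleration else ()):
        for name in KEYPOINT_NAMES:
            names.append(f"{name}_x_{tag}")
            names.append(f"{name}_y_{tag}")
    return tuple(names)


def _position_velocity(snippet: KeypointSnippet, include_acceleration: bool = False):
    """Pre-normalization feature blocks: (frames, 30) per block."""
    pos = preprocess_keypoints(snippet)
    vel = keypoint_velocity(pos)
    n = pos.shape[0]
    blocks = [pos.reshape(n, -1), vel.reshape(n, -1)]
    if include_acceleration:
        blocks.append(keypoint_velocity(vel).reshape(n, -1))
    return blocks


def build_video_features(snippet: KeypointSnippet, stats: NormStats,
                         include_acceleration: bool = False) -> FeatureMatrix:
    """Normalized 250 x 60 feature matrix (x 90 with acceleration columns).

    Positions are z-scored with the pooled training-set ``position`` stats
    and velocities with the ``velocity`` stats; optional accelerations use
    the ``acceleration`` group. Column order: x1p, y1p, ..., x15p, y15p,
    x1v, y1v, ..., y15v (then accelerations if requested).
    """
    groups = ["position", "velocity"] + (["acceleration"] if include_acceleration else [])
    for g in groups:
        if g not in stats:
            raise KeyError(f"NormStats is missing required group {g!r}")
    blocks = _position_velocity(snippet, include_acceleration)
    normalized = [apply_norm(b, g, stats) for b, g in zip(blocks, groups)]
    return FeatureMatrix(
        values=np.concatenate(normalized, axis=1),
        modality=VID,
        channel_names=video_channel_names(include_acceleration),
        meta=snippet.meta,
    )


class VideoFeatureExtractor(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: raw key-point snippets -> video features.

    ``fit`` computes pooled position/velocity (and optionally acceleration)
    z-score statistics over the training snippets; ``transform`` emits one
    (250, 60) matrix per snippet, stacked into (n, 250, 60). Fit only on
    training data — the frozen statistics are then applied unchanged to
    test data.

    Parameters
    ----------
    include_acceleration : bool, default False
        Append 30 key-point acceleration columns (ablation variant).
    """

    def __init__(self, include_acceleration: bool = False):
        self.include_acceleration = include_acceleration

    def _groups(self):
        return ["position", "velocity"] + (
            ["acceleration"] if self.include_acceleration else []
        )

    def fit(self, snippets, y=None):
        pools = {g: [] for g in self._groups()}
        for snip in snippets:
            blocks = _position_velocity(snip, self.include_acceleration)
            for g, b in zip(self._groups(), blocks):
                pools[g].append(b)
        self.norm_stats_ = fit_norm_stats(pools, fitted_on="video-training-pool")
        return self

    def transform_snippet(self, snippet: KeypointSnippet) -> FeatureMatrix:
        return build_video_features(snippet, self.norm_stats_, self.include_acceleration)

    def transform(self, snippets) -> np.ndarray:
        return np.stack([self.transform_snippet(s).values for s in snippets])
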