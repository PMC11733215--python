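"""Center-of-pressure features from the 32 x 32 pressure mat (500 x 6 matrix).

Each 32 x 32 frame is cropped to the 29 x 26 active area (1-based rows
1-29, columns 4-29; 754 cells) and split into a top region (12 x 26,
shoulders/head) and a bottom region (17 x 26, hips). Per region and frame
the pressure-weighted centroid (CoP) and the mean pressure over the full
region area are computed, smoothed with a moving-average filter
(window 5), and normalized per snippet: the four CoP series share the
largest per-series range (gamma), the two mean-pressure series share the
largest pressure range (beta), each series shifted by its own minimum.
All six output series lie in [0, 1].
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .snippets import (
    MAT,
    DegenerateDataError,
    FeatureMatrix,
    PressureSnippet,
    ValidationError,
    _moving_average_columns,
)

__all__ = [
    "crop_and_split", "compute_cop", "normalize_cop", "normalize_pressure",
    "build_mat_features", "PressureMatFeatureExtractor", "mat_channel_names",
    "CROP_ROWS", "CROP_COLS", "TOP_SHAPE", "BOTTOM_SHAPE",
]

logger = logging.getLogger(__name__)

# 1-based inclusive crop [1:29, 4:29] -> 0-based slices; 29*26 = 754 cells.
CROP_ROWS = slice(0, 29)
CROP_COLS = slice(3, 29)
TOP_SHAPE = (12, 26)
BOTTOM_SHAPE = (17, 26)
_SMOOTH_WINDOW = 5


def crop_and_split(snippet: PressureSnippet):
    """Crop each frame to the active area and split into top/bottom regions.

    Returns ``(top, bottom)`` with shapes (frames, 12, 26) and
    (frames, 17, 26).
    """
    values = snippet.values
    if values.shape[1:] != (32, 32):
        raise ValidationError("pressure frames must be 32 x 32")
    crop = values[:, CROP_ROWS, CROP_COLS]
    top = crop[:, : TOP_SHAPE[0], :]
    bottom = crop[:, TOP_SHAPE[0]:, :]
    return top, bottom


def compute_cop(region_frames: np.ndarray):
    """Per-frame CoP coordinates and mean pressure of one region.

    For a frame with cell values p(i, j) (1-based indices), the CoP is
    x = sum_j j p / sum p, y = sum_i i p / sum p, and the mean pressure is
    sum p / (m n) with the full region dimensions as denominator. Frames
    with zero total pressure carry the CoP forward from the last valid
    frame (region centroid if none exists yet); such events are logged.
    """
    region = np.asarray(region_frames, dtype=float)
    if region.ndim != 3:
        raise ValidationError("region must be (frames, m, n)")
    if np.any(region < 0):
        raise ValidationError("negative pressure value in region")
    n_frames, m, n = region.shape
    i_idx = np.arange(1, m + 1, dtype=float)[:, None]
    j_idx = np.arange(1, n + 1, dtype=float)[None, :]

    total = region.sum(axis=(1, 2))
    p = total / (m * n)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.einsum("fij,ij->f", region, np.broadcast_to(j_idx, (m, n))) / total
        y = np.einsum("fij,ij->f", region, np.broadcast_to(i_idx, (m, n))) / total

    empty = total == 0
    if np.any(empty):
        logger.info("%d zero-pressure frame(s) in region; carrying CoP forward",
                    int(empty.sum()))
        cx, cy = (n + 1) / 2.0, (m + 1) / 2.0   # region centroid fallback
        last_x, last_y = cx, cy
        for f in range(n_frames):
            if empty[f]:
                x[f], y[f] = last_x, last_y
            else:
                last_x, last_y = x[f], y[f]
    return x, y, p


def normalize_cop(x_top, y_top, x_bottom, y_bottom):
    """Map the four CoP series into [0, 1] with a shared range normalizer.

    gamma is the largest of the four per-series ranges; each series is
    shifted by its own minimum and divided by gamma, so at least one series
    spans exactly [0, 1]. Degenerate input (no CoP movement at all) raises.
    """
    series = [np.asarray(s, dtype=float) for s in (x_top, y_top, x_bottom, y_bottom)]
    gamma = max(float(s.max() - s.min()) for s in series)
    if gamma <= 0:
        raise DegenerateDataError("all CoP series are constant (gamma = 0)")
    return tuple((s - s.min()) / gamma for s in series), gamma


def normalize_pressure(p_top, p_bottom):
    """Map the two mean-pressure series into [0, 1] with a shared normalizer."""
    series = [np.asarray(s, dtype=float) for s in (p_top, p_bottom)]
    beta = max(float(s.max() - s.min()) for s in series)
    if beta <= 0:
        raise DegenerateDataError("both pressure series are constant (beta = 0)")
    return tuple((s - s.min()) / beta for s in series), beta


def mat_channel_names(include_derivatives: bool = False) -> tuple:
    base = ("x_top", "y_top", "p_top", "x_bottom", "y_bottom", "p_bottom")
    if include_derivatives:
        return base + tuple(f"d_{n}" for n in base)
    return base


def build_mat_features(snippet: PressureSnippet,
                       include_derivatives: bool = False) -> FeatureMatrix:
    """Full chain: crop/split -> CoP -> smoothing -> normalization -> 500 x 6.

    Column order: x_top, y_top, p_top, x_bottom, y_bottom, p_bottom. With
    ``include_derivatives`` the six first-derivative series are appended
    (ablation variant; 12 columns).
    """
    top, bottom = crop_and_split(snippet)
    xt, yt, pt = compute_cop(top)
    xb, yb, pb = compute_cop(bottom)

    smoothed = _moving_average_columns(
        np.column_stack([xt, yt, xb, yb, pt, pb]), _SMOOTH_WINDOW)
    xt, yt, xb, yb, pt, pb = smoothed.T

    (xt, yt, xb, yb), _gamma = normalize_cop(xt, yt, xb, yb)
    (pt, pb), _beta = normalize_pressure(pt, pb)

    columns = np.column_stack([xt, yt, pt, xb, yb, pb])
    if include_derivatives:
        columns = np.concatenate([columns, np.gradient(columns, axis=0)], axis=1)
    return FeatureMatrix(
        values=columns,
        modality=MAT,
        channel_names=mat_channel_names(include_derivatives),
        meta=snippet.meta,
    )


class PressureMatFeatureExtractor(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: pressure snippets -> (n, 500, 6) features.

    Normalization is per snippet (no pooled training statistics), so
    ``fit`` is stateless; it exists for pipeline compatibility.
    """

    def __init__(self, include_derivatives: bool = False):
        self.include_derivatives = include_derivatives

    def fit(self, snippets, y=None):
        self.n_features_out_ = 12 if self.include_derivatives else 6
        return self

    def transform_snippet(self, snippet: PressureSnippet) -> FeatureMatrix:
        return build_mat_features(snippet, self.include_derivatives)

    def transform(self, snippets) -> np.ndarray:
        return np.stack([self.transform_snippet(s).values for s in snippets])
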