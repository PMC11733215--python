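"""Sensor fusion: probability averaging (late) and feature concatenation (early).

Late fusion averages the FM+ probabilities of the per-modality networks
and thresholds the mean at 0.5 (ties go to FM+). Early fusion
temporally harmonizes the pressure-mat (500 frames) and IMU (300 frames)
feature matrices to the video frame count (250) by linear interpolation
and concatenates the columns in the fixed order MAT(6) + IMU(36) +
VID(60), giving one 250 x 102 matrix for a single fused network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .snippets import FUSED, IMU, MAT, VID, FeatureMatrix

__all__ = ["FusionDecision", "late_fuse", "resample_features", "resample_array",
           "early_fuse", "LateFusionClassifier", "FUSION_ORDER",
           "decisions_to_csv"]

FUSION_ORDER = (MAT, IMU, VID)
THRESHOLD = 0.5


@dataclass(frozen=True)
class FusionDecision:
    probabilities: dict          # modality (or net name) -> FM+ probability
    fused_probability: float
    label: int
    threshold: float = THRESHOLD


def late_fuse(probs, names=None) -> FusionDecision:
    """Average 1-3 per-network FM+ probabilities and threshold at 0.5.

    ``fused >= 0.5`` maps to FM+ (the tie goes to FM+; ties are
    measure-zero in practice but must be defined).
    """
    probs = list(probs)
    if not 1 <= len(probs) <= 3:
        raise ValueError("late_fuse expects 1-3 probabilities")
    for p in probs:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0, 1]")
    if names is None:
        names = [f"net{i}" for i in range(len(probs))]
    fused = float(np.mean(probs))
    return FusionDecision(
        probabilities=dict(zip(names, (float(p) for p in probs))),
        fused_probability=fused,
        label=int(fused >= THRESHOLD),
    )


def resample_array(values: np.ndarray, target_frames: int = 250) -> np.ndarray:
    """Linear interpolation of each column onto a uniform grid.

    Works on (frames, channels) or (n, frames, channels); the first and
    last frames are preserved exactly. No anti-aliasing filter is applied
    (the moving-average smoothing upstream already suppresses high
    frequencies).
    """
    values = np.asarray(values, dtype=float)
    frames_axis = values.ndim - 2
    n_frames = values.shape[frames_axis]
    if n_frames < 2 or target_frames < 2:
        raise ValueError("need at least 2 frames on both sides of the resampling")
    pos = np.linspace(0.0, n_frames - 1, target_frames)
    i0 = np.floor(pos).astype(int)
    i1 = np.minimum(i0 + 1, n_frames - 1)
    w = pos - i0
    if values.ndim == 2:
        return values[i0] * (1 - w)[:, None] + values[i1] * w[:, None]
    return (values[:, i0] * (1 - w)[None, :, None]
            + values[:, i1] * w[None, :, None])


def resample_features(fm: FeatureMatrix, target_frames: int = 250) -> FeatureMatrix:
    """Resample one feature matrix to ``target_frames`` rows (channels unchanged)."""
    return FeatureMatrix(
        values=resample_array(fm.values, target_frames),
        modality=fm.modality,
        channel_names=fm.channel_names,
        meta=fm.meta,
    )


def early_fuse(mats) -> FeatureMatrix:
    """Concatenate per-modality matrices column-wise in MAT, IMU, VID order.

    All inputs must already share one frame count (use
    :func:`resample_features` first); with the default three modalities
    the result is 250 x 102. The column blocks are bit-identical to the
    inputs.
    """
    mats = list(mats)
    if not mats:
        raise ValueError("early_fuse needs at least one feature matrix")
    rank = {m: i for i, m in enumerate(FUSION_ORDER)}
    mats.sort(key=lambda fm: rank.get(fm.modality, len(FUSION_ORDER)))
    frame_counts = {fm.modality: fm.n_frames for fm in mats}
    if len(set(frame_counts.values())) != 1:
        raise ValueError(f"frame-count mismatch between modalities: {frame_counts}")
    return FeatureMatrix(
        values=np.concatenate([fm.values for fm in mats], axis=1),
        modality=FUSED,
        channel_names=tuple(
            f"{fm.modality.lower()}_{name}" for fm in mats for name in fm.channel_names
        ),
        meta=mats[0].meta,
    )


def decisions_to_csv(decisions: dict, path):
    """Export ``{snippet_id: FusionDecision}`` as a tidy CSV.

    Columns: snippet_id, one probability column per network, the fused
    probability and the thresholded label.
    """
    import pandas as pd

    rows = []
    for snippet_id, d in decisions.items():
        row = {"snippet_id": snippet_id, **d.probabilities,
               "fused_probability": d.fused_probability, "label": d.label}
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)
    return path


class LateFusionClassifier(ClassifierMixin, BaseEstimator):
    """Probability-averaging ensemble over pre-fitted per-modality classifiers.

    ``estimators`` maps a name to a fitted classifier exposing
    ``predict_proba``; ``predict_proba`` of the ensemble is the arithmetic
    mean, and ``predict`` applies the 0.5 threshold (ties to FM+).
    The per-modality inputs are passed as a dict name -> X.
    """

    def __init__(self, estimators: dict):
        self.estimators = estimators

    def fit(self, X=None, y=None):
        return self

    def predict_proba(self, X: dict) -> np.ndarray:
        probs = np.mean(
            [self.estimators[name].predict_proba(X[name])[:, 1]
             for name in self.estimators], axis=0)
        return np.column_stack([1.0 - probs, probs])

    def predict(self, X: dict) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= THRESHOLD).astype(int)
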