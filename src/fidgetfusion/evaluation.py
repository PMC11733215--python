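"""Subject-disjoint cross-validation and statistical comparison of models.

Evaluation follows the study protocol: infants are partitioned into k
disjoint subsets (9 folds x 4 infants by default); every snippet of an
infant stays on one side of each fold, so test infants are never seen in
training. Per fold and model the confusion counts yield sensitivity
(TPR), specificity (TNR) and balanced accuracy BA = (TPR + TNR)/2;
models are compared pairwise with an exact two-sided Wilcoxon
signed-rank test on the per-fold balanced accuracies, and fold means are
reported with Student-t 95% confidence intervals.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import fusion as fusion_mod
from .classifier import CNNConfig, TrainConfig, predict_proba, train_with_restarts
from .imu import ACCEL_COLUMNS, GYRO_COLUMNS, _smoothed_centered
from .mat import build_mat_features
from .snippets import (
    IMU,
    MAT,
    VID,
    Dataset,
    filter_synchronized,
)
from .video import _position_velocity

__all__ = [
    "ConfusionCounts", "FoldResult", "ModelSpec", "CVReport",
    "make_folds", "classification_metrics", "mean_ci95",
    "wilcoxon_exact", "cohen_kappa", "run_crossval",
]


class MetricUndefinedError(ValueError):
    """Raised when a metric is undefined (e.g. a class absent from the test set)."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            TP=int(np.sum((y_true == 1) & (y_pred == 1))),
            TN=int(np.sum((y_true == 0) & (y_pred == 0))),
            FP=int(np.sum((y_true == 0) & (y_pred == 1))),
            FN=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


def classification_metrics(counts: ConfusionCounts):
    """(TPR, TNR, BA) from confusion counts; errors if a class is empty."""
    if counts.TP + counts.FN == 0:
        raise MetricUndefinedError("no FM+ snippets in the test set (TPR undefined)")
    if counts.TN + counts.FP == 0:
        raise MetricUndefinedError("no FM- snippets in the test set (TNR undefined)")
    tpr = counts.TP / (counts.TP + counts.FN)
    tnr = counts.TN / (counts.TN + counts.FP)
    return tpr, tnr, (tpr + tnr) / 2.0


def mean_ci95(values):
    """(mean, lower, upper) Student-t 95% CI of the mean (df = n - 1)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values for a confidence interval")
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / np.sqrt(values.size))
    half = float(sps.t.ppf(0.975, values.size - 1) * sem)
    return mean, mean - half, mean + half


_EXACT_LIMIT = 15


def wilcoxon_exact(a, b):
    """Two-sided Wilcoxon signed-rank test with exact small-sample p-values.

    Zero differences are dropped (Wilcoxon's original treatment); absolute
    differences are ranked with mid-ranks for ties; W is the sum of the
    positive-difference ranks. For m <= 15 retained pairs the null
    distribution is enumerated over all 2^m sign assignments of the actual
    rank multiset (exact even under ties); above that a normal
    approximation with tie correction is used. Returns (W, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("paired samples of equal length >= 1 required")
    d = a - b
    d = d[d != 0]
    m = d.size
    if m == 0:
        raise MetricUndefinedError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())

    if m <= _EXACT_LIMIT:
        # doubled ranks are integers even with midranks
        r2 = np.round(2 * ranks).astype(np.int64)
        w2 = int(round(2 * w))
        signs = (np.arange(2 ** m, dtype=np.uint32)[:, None]
                 >> np.arange(m, dtype=np.uint32)) & 1
        sums = signs.astype(np.int64) @ r2
        p_le = float(np.mean(sums <= w2))
        p_ge = float(np.mean(sums >= w2))
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean = m * (m + 1) / 4.0
        tie_counts = np.unique(np.abs(d), return_counts=True)[1]
        var = (m * (m + 1) * (2 * m + 1) / 24.0
               - float(((tie_counts ** 3 - tie_counts) / 48.0).sum()))
        z = (w - mean) / np.sqrt(var)
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return w, p


def cohen_kappa(labels_a, labels_b) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e) from two label sequences."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("label sequences of equal length >= 1 required")
    cats = np.unique(np.concatenate([a, b]))
    if cats.size < 2:
        raise MetricUndefinedError("need >= 2 observed categories for kappa")
    p_o = float(np.mean(a == b))
    p_e = float(sum(np.mean(a == c) * np.mean(b == c) for c in cats))
    if p_e >= 1.0:
        raise MetricUndefinedError("chance agreement is 1; kappa undefined")
    return (p_o - p_e) / (1.0 - p_e)


def make_folds(dataset: Dataset, k: int = 9, infants_per_fold: int = 4,
               seed: int = 0):
    """Seeded random partition of infants into k disjoint test subsets.

    Returns ``[(train_infants, test_infants), ...]``; requires exactly
    ``k * infants_per_fold`` infants.
    """
    infants = sorted(set(dataset.infant_ids))
    if len(infants) != k * infants_per_fold:
        raise ValueError(
            f"{len(infants)} infants cannot form {k} folds of {infants_per_fold}")
    order = np.random.default_rng(seed).permutation(len(infants))
    shuffled = [infants[i] for i in order]
    folds = []
    for f in range(k):
        test = tuple(shuffled[f * infants_per_fold:(f + 1) * infants_per_fold])
        train = tuple(x for x in shuffled if x not in test)
        folds.append((train, test))
    return folds


# ---------------------------------------------------------------------------
# Cross-validated model comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One model to evaluate: which modalities, how fused, which CNN.

    ``fusion``: "single" (one modality), "late" (average per-modality
    network probabilities) or "early" (one network on the concatenated
    250-frame matrix). ``config`` is one CNNConfig, or — for late fusion
    with per-modality architectures — a mapping modality -> CNNConfig, so
    the fused model shares the exact networks of the single-modality
    specs (run_crossval trains each distinct (modality, config) pair
    once per fold).
    """

    modalities: tuple
    fusion: str = "single"
    config: CNNConfig | dict = field(default_factory=CNNConfig)

    def __post_init__(self):
        object.__setattr__(self, "modalities", tuple(self.modalities))
        if isinstance(self.config, dict):
            object.__setattr__(self, "config",
                               tuple(sorted(self.config.items())))
        if self.fusion not in ("single", "late", "early"):
            raise ValueError(f"unknown fusion mode {self.fusion!r}")
        if self.fusion == "single" and len(self.modalities) != 1:
            raise ValueError("single-modality spec must name exactly one modality")

    def config_for(self, modality: str) -> CNNConfig:
        if isinstance(self.config, tuple):
            return dict(self.config)[modality]
        return self.config


@dataclass(frozen=True)
class FoldResult:
    fold_index: int
    test_infants: tuple
    counts: ConfusionCounts
    TPR: float
    TNR: float
    BA: float


@dataclass
class CVReport:
    """Per-model fold results, summary statistics and pairwise Wilcoxon p-values."""

    folds: dict                      # model name -> [FoldResult, ...]
    summary: dict                    # model name -> {metric: (mean, lo, hi)}
    pairwise_p: dict                 # frozenset({a, b}) -> p-value
    k: int
    seed: int

    def mean_ba(self, model: str) -> float:
        return self.summary[model]["BA"][0]

    def p_value(self, model_a: str, model_b: str) -> float:
        return self.pairwise_p[frozenset((model_a, model_b))]

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for model, metrics in self.summary.items():
            row = {"model": model}
            for metric, (mean, lo, hi) in metrics.items():
                row[metric] = mean
                row[f"{metric}_ci_low"] = lo
                row[f"{metric}_ci_high"] = hi
            rows.append(row)
        return pd.DataFrame(rows).set_index("model")

    def pairwise_frame(self) -> pd.DataFrame:
        names = list(self.folds)
        table = pd.DataFrame(np.nan, index=names, columns=names)
        for (a, b), p in ((tuple(sorted(key)), p)
                          for key, p in self.pairwise_p.items()):
            table.loc[a, b] = p
            table.loc[b, a] = p
        return table

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "folds": {
                model: [
                    {
                        "fold_index": fr.fold_index,
                        "test_infants": list(fr.test_infants),
                        "counts": {"TP": fr.counts.TP, "TN": fr.counts.TN,
                                   "FP": fr.counts.FP, "FN": fr.counts.FN},
                        "TPR": fr.TPR, "TNR": fr.TNR, "BA": fr.BA,
                    }
                    for fr in results
                ]
                for model, results in self.folds.items()
            },
            "summary": {
                model: {metric: list(ci) for metric, ci in metrics.items()}
                for model, metrics in self.summary.items()
            },
            "pairwise_p": [
                {"models": sorted(key), "p": p} for key, p in self.pairwise_p.items()
            ],
        }

    def save(self, out_dir) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "cv_report.json").write_text(json.dumps(self.to_dict(), indent=1))
        self.summary_frame().to_csv(out_dir / "cv_summary.csv")
        self.pairwise_frame().to_csv(out_dir / "cv_pairwise_p.csv")
        return out_dir / "cv_report.json"


def _vid_prenorm(triples):
    """(n, 250, 60) pre-normalization position+velocity blocks."""
    return np.stack([
        np.concatenate(_position_velocity(t.keypoints), axis=1) for t in triples
    ])


def _imu_prenorm(triples):
    return np.stack([_smoothed_centered(t.imu) for t in triples])


def _mat_feats(triples):
    return np.stack([build_mat_features(t.pressure).values for t in triples])


def _pooled_scale(block: np.ndarray):
    """Pooled mean/sd over every entry of a training block (population sd)."""
    mean = float(block.mean())
    sd = float(block.std(ddof=0))
    if not sd > 0:
        raise ValueError("zero pooled variance in training block")
    return mean, sd


def _normalize_fold(modality, prenorm, train_mask):
    """Fold-wise z-scoring with stats fitted on the training side only."""
    if modality == MAT:
        return prenorm                       # per-snippet normalization already done
    out = np.empty_like(prenorm)
    if modality == VID:
        groups = ((slice(0, 30),), (slice(30, 60),))
    else:
        groups = ((ACCEL_COLUMNS,), (GYRO_COLUMNS,))
    for (cols,) in groups:
        mean, sd = _pooled_scale(prenorm[train_mask][:, :, cols])
        out[:, :, cols] = (prenorm[:, :, cols] - mean) / sd
    return out


def _derive_seed(master: int, *key) -> int:
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=tuple(int(x) for x in key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_crossval(dataset: Dataset, model_specs: dict, tc: TrainConfig,
                 k: int = 9, infants_per_fold: int = 4, seed: int = 0) -> CVReport:
    """Subject-disjoint k-fold evaluation of one or more model specs.

    Per fold: normalization statistics are fitted on the training snippets
    only, one network is trained per required modality (shared between a
    single-modality spec and any late-fusion spec using the same
    architecture) with ``tc.n_restarts`` restarts, test snippets are
    scored, fused as specified, and thresholded at 0.5. Restart seeds
    derive deterministically from (seed, fold, network).
    """
    required = frozenset(m for spec in model_specs.values() for m in spec.modalities)
    ds = filter_synchronized(dataset, required)
    triples = list(ds)
    labels = ds.labels
    infant_of = np.array([t.meta.infant_id for t in triples])

    prenorm = {}
    if VID in required:
        prenorm[VID] = _vid_prenorm(triples)
    if IMU in required:
        prenorm[IMU] = _imu_prenorm(triples)
    if MAT in required:
        prenorm[MAT] = _mat_feats(triples)

    folds = make_folds(ds, k=k, infants_per_fold=infants_per_fold, seed=seed)
    fold_results = {name: [] for name in model_specs}

    for f, (train_infants, test_infants) in enumerate(folds):
        train_mask = np.isin(infant_of, train_infants)
        test_mask = np.isin(infant_of, test_infants)
        assert not np.any(train_mask & test_mask), "infant leaked across the fold split"

        normalized = {
            m: _normalize_fold(m, prenorm[m], train_mask) for m in prenorm
        }

        # train each distinct network for this fold once; late fusion reuses
        # the single-modality networks, mirroring the multi-network design
        nets = {}

        def _net(net_key, X):
            if net_key not in nets:
                # nets are numbered in first-use order, which is fixed by the
                # insertion order of model_specs -> reproducible seeds
                net_seed = _derive_seed(seed, f, len(nets))
                fitted = train_with_restarts(
                    X[train_mask], labels[train_mask].astype(float),
                    replace(net_key[1], input_shape=X.shape[1:]),
                    replace(tc, seed=net_seed))
                nets[net_key] = predict_proba(fitted, X[test_mask])
            return nets[net_key]

        for name, spec in model_specs.items():
            if spec.fusion == "early":
                blocks = [
                    normalized[m] if m == VID
                    else fusion_mod.resample_array(normalized[m], 250)
                    for m in fusion_mod.FUSION_ORDER if m in spec.modalities
                ]
                X = np.concatenate(blocks, axis=2)
                probs = _net((("EARLY",) + tuple(spec.modalities),
                              spec.config_for(spec.modalities[0])), X)
            else:
                per_mod = [
                    _net(((m,), spec.config_for(m)), normalized[m])
                    for m in spec.modalities
                ]
                probs = np.mean(per_mod, axis=0)
            preds = (probs >= fusion_mod.THRESHOLD).astype(int)
            counts = ConfusionCounts.from_predictions(labels[test_mask], preds)
            try:
                tpr, tnr, ba = classification_metrics(counts)
            except MetricUndefinedError:
                tpr = tnr = ba = float("nan")
            fold_results[name].append(FoldResult(
                fold_index=f, test_infants=tuple(test_infants), counts=counts,
                TPR=tpr, TNR=tnr, BA=ba))

    summary = {}
    for name, results in fold_results.items():
        metrics = {}
        for metric in ("TPR", "TNR", "BA"):
            vals = np.array([getattr(r, metric) for r in results], dtype=float)
            vals = vals[~np.isnan(vals)]
            metrics[metric] = mean_ci95(vals) if vals.size >= 2 else (
                float(vals.mean()) if vals.size else float("nan"), float("nan"),
                float("nan"))
        summary[name] = metrics

    pairwise = {}
    for a, b in itertools.combinations(model_specs, 2):
        ba_a = np.array([r.BA for r in fold_results[a]])
        ba_b = np.array([r.BA for r in fold_results[b]])
        ok = ~(np.isnan(ba_a) | np.isnan(ba_b))
        try:
            _, p = wilcoxon_exact(ba_a[ok], ba_b[ok])
        except (MetricUndefinedError, ValueError):
            p = float("nan")
        pairwise[frozenset((a, b))] = p

    return CVReport(folds=fold_results, summary=summary, pairwise_p=pairwise,
                    k=k, seed=seed)
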