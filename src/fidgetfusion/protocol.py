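"""Frozen desk-scale benchmark protocol on synthetic cohorts.

This module pins down the three reference study conditions used by the
package's own end-to-end checks, so tests, scripts and users run the
identical experiment:

* ``strong``  — 36 infants x 20 snippets, a clear shared fidgety signal
  (every modality alone should classify well);
* ``split``   — the class signal is divided into three independent
  per-modality components, each deliberately weak, to probe whether late
  fusion beats every single modality;
* ``null``    — no fidgety component at all; subject-disjoint CV must
  hover at chance (negative control for information leakage).

The CNN interiors are small per-modality choices (the mat network gets
longer kernels because its 100 Hz CoP series need a wider temporal
receptive field), and the optimization protocol is scaled for a single
CPU: batch 32, learning rate 3e-3, patience 3, at most 10 epochs and 3
restarts. Everything remains overridable through the regular configs.
"""

from __future__ import annotations

import numpy as np

from .classifier import CNNConfig, TrainConfig
from .evaluation import CVReport, ModelSpec, run_crossval
from .simulate import SimConfig, generate_dataset
from .snippets import IMU, MAT, VID

__all__ = [
    "modality_cnn_config", "desk_train_config", "cohort_config",
    "benchmark_model_specs", "run_benchmark", "chance_band",
]

_MODALITY_CNN = {
    VID: CNNConfig(conv_layers=((8, 7), (8, 7), (8, 5)), fc_units=16),
    MAT: CNNConfig(conv_layers=((8, 11), (8, 11), (8, 5)), fc_units=16),
    IMU: CNNConfig(conv_layers=((8, 5), (8, 5), (8, 5)), fc_units=16),
}


def modality_cnn_config(modality: str) -> CNNConfig:
    """Small per-modality CNN used by the benchmark protocol."""
    return _MODALITY_CNN[modality]


def desk_train_config(seed: int, n_restarts: int = 3) -> TrainConfig:
    """Single-CPU training protocol for the benchmark cohorts."""
    return TrainConfig(batch_size=32, learning_rate=3e-3, patience=3,
                       max_epochs=10, n_restarts=n_restarts, seed=seed)


def cohort_config(kind: str, seed: int) -> SimConfig:
    """Study conditions of the three reference cohorts."""
    if kind == "strong":
        return SimConfig(seed=seed)
    if kind == "split":
        return SimConfig(fidgety_amp=9.0, split_signal=True, seed=seed)
    if kind == "null":
        return SimConfig(fidgety_amp=0.0, seed=seed)
    raise ValueError(f"unknown cohort kind {kind!r}")


def benchmark_model_specs(fusion: bool = True) -> dict:
    """Single-modality specs (plus the three-network late fusion)."""
    specs = {
        m: ModelSpec(modalities=(m,), fusion="single",
                     config=modality_cnn_config(m))
        for m in (MAT, IMU, VID)
    }
    if fusion:
        # late fusion carries the per-modality configs, so run_crossval
        # reuses the single-modality networks — the multi-network reading
        # of late fusion
        specs["ALL-3"] = ModelSpec(
            modalities=(MAT, IMU, VID), fusion="late",
            config={m: modality_cnn_config(m) for m in (MAT, IMU, VID)})
    return specs


def run_benchmark(kind: str, seed: int, k: int = 9,
                  infants_per_fold: int = 4) -> CVReport:
    """Generate the cohort and run the subject-disjoint CV for one condition.

    ``strong`` evaluates the three single modalities; ``split`` adds the
    three-network late fusion; ``null`` evaluates the video network only
    (one restart — model selection is irrelevant without signal).
    """
    cfg = cohort_config(kind, seed)
    dataset = generate_dataset(cfg)
    if kind == "null":
        specs = {VID: ModelSpec(modalities=(VID,), fusion="single",
                                config=modality_cnn_config(VID))}
        tc = desk_train_config(seed, n_restarts=1)
        tc = TrainConfig(**{**tc.to_dict(), "max_epochs": 6})
    else:
        specs = benchmark_model_specs(fusion=(kind == "split"))
        tc = desk_train_config(seed)
    return run_crossval(dataset, specs, tc, k=k,
                        infants_per_fold=infants_per_fold, seed=seed)


def chance_band(report: CVReport, model: str, level_z: float = 1.96):
    """95% band around 0.5 for the mean balanced accuracy of a chance
    predictor, from the per-fold class counts actually evaluated.

    Var(BA) per fold is (1/4)(1/(4 n_pos) + 1/(4 n_neg)) for a coin-flip
    predictor; fold means are independent.
    """
    variances = []
    for fr in report.folds[model]:
        n_pos = fr.counts.TP + fr.counts.FN
        n_neg = fr.counts.TN + fr.counts.FP
        variances.append(0.25 * (0.25 / n_pos + 0.25 / n_neg))
    half = level_z * float(np.sqrt(np.sum(variances)) / len(variances))
    return 0.5 - half, 0.5 + half
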