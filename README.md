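# fidgetfusion

Multimodal sensor fusion for classifying infant fidgety movements.

The general movement assessment (GMA) evaluates an infant's spontaneous
motor patterns to screen for neurological impairment in the first
months of life; around three months post-term the key pattern is the
presence (FM+) or absence (FM−) of *fidgety movements* — small,
moderate-frequency movements superimposed on ongoing motility.
`fidgetfusion` implements an automated pipeline for this binary
classification from 5-second snippets recorded by three synchronized
sensors:

* **VID** — 2D pose key points from video (250 frames × 15 points),
* **MAT** — a 32 × 32 pressure-sensing mat (500 frames),
* **IMU** — six inertial units on shoulders, hips and feet (300 frames ×
  6 channels),

and asks the question the multimodal design exists for: does fusing
modalities beat each single one?

## Method in brief

Per snippet, each modality is reduced to a frames × channels feature
matrix:

* video: skeleton normalization (median+moving-average smoothing;
  centering on the mean hip midpoint h^c; rotation of the trunk midline
  onto +Y; scaling so |h^c − s^c| = 1/3; per-series mean centering),
  positions + central-difference velocities, pooled z-scores → 250 × 60;
* mat: crop to the 29 × 26 active area (754 cells), split into top
  (shoulders) and bottom (hips) regions, per-frame center of pressure
  x = Σ j·p(i,j)/Σ p(i,j), y = Σ i·p(i,j)/Σ p(i,j) and mean pressure
  p = Σ p(i,j)/(m·n), smoothed and range-normalized per snippet →
  500 × 6;
* IMU: smoothing, per-series mean centering (removes gravity), grouped
  z-scores for acceleration vs angular velocity → 300 × 36.

Each matrix is classified by a compact 1-D temporal CNN (3 conv + 1 FC
layer, batch norm, 20 % dropout, linear output unit, binary
cross-entropy on the logit, Adam, validation stop, best-of-n restarts)
implemented from scratch in NumPy. **Late fusion** averages the
per-modality FM+ probabilities p̄ = (p_MAT + p_IMU + p_VID)/3 and
thresholds at 0.5; **early fusion** resamples everything to 250 frames
and trains one network on the concatenated 250 × 102 matrix. Models are
compared by subject-disjoint 9-fold cross-validation (no infant on both
sides of any fold) with sensitivity, specificity, balanced accuracy
BA = (TPR + TNR)/2, Student-t 95 % CIs, and exact two-sided Wilcoxon
signed-rank tests on per-fold BA. A seeded synthetic tri-modal movement
simulator makes the entire pipeline runnable and testable without any
recordings. See `docs/methods.md` for the full account.

## Worked example

The CLI ties simulation, feature extraction, training and evaluation
together; every command writes a provenance record (config, seeds,
artifact hashes). With this `config.yaml`:

```yaml
seed: 7
simulate: {n_infants: 8, snippets_per_infant: 16}
model: {conv_layers: [[8, 7], [8, 7], [8, 5]], fc_units: 16}
train: {batch_size: 8, learning_rate: 0.002, max_epochs: 25, patience: 6, n_restarts: 2}
crossval:
  k: 4
  infants_per_fold: 2
  models:
    VID: {modalities: [VID]}
    IMU: {modalities: [IMU]}
    ALL-3: {modalities: [MAT, IMU, VID], fusion: late}
```

```sh
fidgetfusion simulate --config config.yaml --out data
fidgetfusion crossval --config config.yaml --data data --out cv
fidgetfusion report --data cv
```

prints (a few minutes on one CPU):

```
4-fold subject-disjoint cross-validation (seed 7)

model              Sens.   Spec.      BA   95% CI (BA)
VID                0.880   0.866   0.873   [0.781 0.965]
IMU                0.987   1.000   0.993   [0.972 1.014]
ALL-3              1.000   0.944   0.972   [0.909 1.034]

pairwise Wilcoxon signed-rank p-values (per-fold BA):
  IMU vs VID: p = 0.1250
  ALL-3 vs VID: p = 0.1250
  ALL-3 vs IMU: p = 0.5000
```

Reading: on this small synthetic cohort every snippet is classified per
modality, per-fold confusion counts give sensitivity/specificity/BA,
and the signed-rank test compares models on the four per-fold BAs (with
n = 4 folds the smallest attainable two-sided p is 0.125 — only the
full 9-fold protocol can reach conventional significance). The t-based
CI can exceed 1; it is an interval for the mean, not a coverage claim
for BA itself.

The library is usable directly as scikit-learn-style estimators:

```python
from fidgetfusion import (SimConfig, generate_dataset,
                          VideoFeatureExtractor, CNNSnippetClassifier)

cohort = generate_dataset(SimConfig(n_infants=8, snippets_per_infant=16, seed=7))
kp = [t.keypoints for t in cohort]
X = VideoFeatureExtractor().fit(kp).transform(kp)   # (128, 250, 60)
clf = CNNSnippetClassifier(conv_layers=((8, 7), (8, 7), (8, 5)), fc_units=16,
                           n_restarts=2, max_epochs=25, random_state=0)
clf.fit(X[:96], cohort.labels[:96])
proba = clf.predict_proba(X[96:])[:, 1]             # FM+ probabilities
```

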