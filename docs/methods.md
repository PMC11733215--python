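# Methods

## Problem and pipeline

`fidgetfusion` classifies 5-second snippets of spontaneous infant
movement as containing fidgety movements (FM+, label 1) or not (FM−,
label 0) from three synchronized sensor modalities, and asks whether
fusing the modalities beats any one of them. The pipeline per snippet:

1. **Video (VID).** 250 frames (50 Hz) of 15 pose key points (the 17
   COCO points minus the ears). Each coordinate series is passed through
   a running median and then a moving average, both with a centered
   window of 5 frames; the skeleton is centered on the time-averaged hip
   midpoint, rotated so the hip→shoulder midline lies on the +Y axis,
   scaled so the trunk length is 1/3, and each series is mean-centered.
   Central-difference velocities are appended and positions/velocities
   are z-scored with statistics pooled over the *training* snippets
   only. Result: 250 × 60 (x/y interleaved positions, then velocities;
   optionally 30 acceleration columns).
2. **Pressure mat (MAT).** 500 frames (100 Hz) of a 32 × 32 grid. Each
   frame is cropped to the 29 × 26 active area (754 cells, 1-based rows
   1–29 and columns 4–29) and split at row 12 into a top (shoulders /
   head) and bottom (hips) region. Per region and frame the
   pressure-weighted centroid (CoP) and the mean pressure over the fixed
   region area are computed, smoothed (moving average, window 5) and
   mapped to [0, 1] per snippet: the four CoP series share one
   normalizer γ (the largest per-series range), the two pressure series
   share β. Result: 500 × 6.
3. **IMU.** 300 frames (60 Hz) × 6 sensors (shoulders, hips, feet) × 6
   channels (acceleration triplet, then gyro triplet). Each of the 36
   series is smoothed (moving average, window 5) and mean-centered —
   which removes the constant gravity offset — then accelerations and
   angular velocities are z-scored separately with pooled training
   statistics. Result: 300 × 36.

Each matrix feeds a compact 1-D temporal CNN (three convolutions over
the frame axis with the feature columns as channels, each followed by
batch normalization, ReLU and 20 % dropout; one fully connected layer
with the same trimmings; a single linear output unit). The loss is
binary cross-entropy on the logit; the optimizer Adam. **Late fusion**
averages the FM+ probabilities of the per-modality networks and
thresholds the mean at 0.5 (ties → FM+). **Early fusion** resamples MAT
and IMU features to 250 frames by linear interpolation and concatenates
MAT(6) + IMU(36) + VID(60) into one 250 × 102 matrix for a single
network.

## Statistical protocol

Evaluation is subject-disjoint 9-fold cross-validation: infants are
partitioned into nine disjoint subsets of four; every snippet of an
infant stays on one side of each fold. Per fold, normalization
statistics are refitted on the training side only; each network is
trained with a validation stop (the last 1/8 of a seeded shuffle held
out; stop when the validation loss has not improved for the patience)
and the training is restarted from fresh initial weights several times,
keeping the lowest-validation-loss network. Metrics are sensitivity
TPR = TP/(TP+FN), specificity TNR = TN/(TN+FP) and balanced accuracy
BA = (TPR+TNR)/2, reported with Student-t 95 % confidence intervals over
the nine folds. Models are compared with a two-sided Wilcoxon
signed-rank test on per-fold BA: zero differences dropped, mid-ranks for
ties, and for m ≤ 15 retained pairs the p-value is computed by exact
enumeration of all 2^m sign assignments of the realized rank multiset
(above that, a normal approximation with tie correction). For n = 9
untied folds the attainable two-sided p-values are the grid {2k/512};
the extremes 2/512 ≈ 0.0039 and 4/512 ≈ 0.0078 serve as analytic
anchors. Cohen's κ = (p_o − p_e)/(1 − p_e) is provided for interrater
agreement analyses.

Choices worth making explicit:

* pooled z-scores use the population SD (divide by N); position x and y
  values share one pool, as do velocity values ("across all position
  (or velocity) time series");
* both smoothing filters use truncated, shrinking centered windows at
  the series edges, preserving length without inventing data;
* the skeleton rotation uses the signed angle `atan2(sc_x, sc_y)`, so
  left- and right-tilted skeletons both land on +Y (an unsigned `acos`
  would mirror one direction);
* velocities are central differences in units of position/frame
  (forward/backward at the edges); the constant frame-rate factor is
  absorbed by z-scoring;
* MAT frames with zero total pressure in a region carry the CoP forward
  from the last valid frame (region centroid if none); the event is
  logged;
* the CI uses Student-t with df = 8 rather than a normal quantile
  (n = 9);
* CV fold membership is a seeded random partition of infants;
* the 0.5 threshold maps the tie p̄ = 0.5 to FM+.

## The CNN implementation

No deep-learning framework is used: the networks are implemented
directly in NumPy (`fidgetfusion.nn`) with exact manual backpropagation
(verified against finite differences in the test suite). Convolutions
are same-padding, stride 1, realized as im2col + BLAS matmul; batch
normalization uses ε = 1e-3 and running-statistics momentum 0.99;
dropout is inverted (identity at inference). All parameters and
activations are float32 — the models are small and memory-bandwidth
bound, and single precision is the norm for CNN training. Training is
bit-reproducible from the seed within a platform; the reproducibility
contract for losses is ≤ 1e-6.

Defaults follow the recording-study protocol: Adam with batch size 4,
learning rate 0.001, β₁ = 0.9, β₂ = 0.999, ε = 1e-07; validation split
1/8; patience 10; 20 restarts. The default architecture interior
(32, 64, 64 kernels of size 5; 64 FC units) is a sane mid-sized choice —
the per-modality architecture search that would pin it down is out of
scope, so everything is exposed through `CNNConfig`/`TrainConfig`.

## Synthetic cohorts

The generator (`fidgetfusion.simulate`) emulates the recording geometry,
not infant biomechanics. Latent limb/trunk trajectories are sums of
random-phase sinusoids: every snippet carries slow baseline oscillations
(0.1–0.5 Hz, default amplitude 40 px, distal key points weighted
highest), and FM+ snippets additionally carry a small-amplitude
moderate-frequency component (1–3 Hz, default 12 px). The same latent
trajectories drive all three renderings, so modalities are naturally
correlated:

* **key points** = canonical supine skeleton + displacements + Gaussian
  noise (1.5 px) + sparse one-frame outlier spikes (rate 0.002,
  ±120 px), in a y-up pixel frame;
* **pressure** = two Gaussian load blobs (σ = 3 cells, intensity 10)
  tracking the shoulder and hip midpoints, with a ground-reaction
  coupling: blob position and intensity also follow the mean wrist
  (top) and ankle (bottom) accelerations. Differentiation amplifies the
  fidgety band by its squared angular frequency, which is what makes
  the range-normalized CoP features class-informative — without it the
  per-snippet [0, 1] normalization leaves only a subtle spectral cue
  that small CNNs fail to pick up. Sensor noise sd 0.5, clipped at 0,
  stored as float32;
* **IMU** = per-sensor acceleration as the second finite difference of
  the attachment-point trajectory × rate², plus a constant random
  gravity vector (magnitude 500 in the same arbitrary units; removed
  exactly by per-series centering) and noise (sd 40); angular velocity
  as the first difference of the segment angle × rate, distributed over
  the three gyro axes by a fixed per-sensor unit vector.

Per-infant amplitude effects are LogNormal(0, 0.2); labels are i.i.d.
Bernoulli(0.56), matching the class prevalence of the kind of annotated
cohort the package targets; sessions are T1 for FM− and T5–T7 for FM+.
Each modality can be deleted independently (`missing_modality_rate`) to
exercise the synchronization filter. One master seed drives everything;
per-snippet `SeedSequence` substreams make any snippet regenerable in
isolation. With `fidgety_amp = 0` the FM+ and FM− generator paths are
identical, so the two classes are literally the same distribution.

`split_signal = True` replaces the shared fidgety component with three
independent ones — one rendered only into the key points, one only into
the pressure blobs, one only into the IMU streams — so that each
modality alone carries a weak signal and fusion has something to gain.
The MAT-only and IMU-only components are damped (× 0.62 and × 0.22)
to keep the three single-modality difficulties comparable; without the
IMU damping the differentiation advantage saturates that channel.

What the simulator does *not* emulate: realistic infant kinematics or
contact mechanics, pose-estimation failure modes beyond sparse spikes,
sensor drift, or session effects. Passing benchmarks on these cohorts
demonstrates that the pipeline, training protocol and statistics behave
correctly — not that the classifier reaches any particular accuracy on
real recordings.

## Desk-scale benchmark protocol

`fidgetfusion.protocol` freezes three reference conditions on cohorts of
36 infants × 20 snippets (the size a 9 × 4 subject-disjoint CV needs):
`strong` (shared signal, every modality alone should classify well),
`split` (independent weak per-modality signals; late fusion should beat
every single modality), and `null` (no signal; CV must stay inside the
95 % chance band computed from the realized fold class counts). To fit a
single CPU, the protocol uses small per-modality CNNs — VID kernels
(7, 7, 5), MAT (11, 11, 5) (the 100 Hz CoP series need a wider temporal
receptive field), IMU (5, 5, 5); 8 kernels per layer, 16 FC units — and
batch 32, learning rate 3e-3, patience 3, at most 10 epochs, 3 restarts
(1 restart and 6 epochs for the null control, where model selection is
moot). These are runtime-scale choices, not tuned quantities; the
full-size defaults remain available through the regular configs.

## Known limitations

* The acceleration/derivative ablation columns are implemented and
  tested but not part of the benchmark protocol.
* The Wilcoxon normal approximation (m > 15) applies no continuity
  correction; the exact path covers every case the protocol produces.
* `Dataset` holds raw arrays in memory (~2 GiB for a 720-snippet
  tri-modal cohort with float32 pressure); streaming ingestion is out
  of scope.
* Early fusion requires all modalities present at inference; late
  fusion degrades gracefully by averaging whatever networks are given.
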