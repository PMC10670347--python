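# Methods

## The model

`hilofuse` implements a multimodal classifier for major depressive disorder
(MDD) versus healthy controls (HC) that deliberately separates image
information by spatial frequency before fusing it:

* **MHFE — meta-high-frequency encoder.** A lightweight fully convolutional
  3D network (SFCN-style): four blocks of 3×3×3 convolution (padding 1) →
  BatchNorm → ReLU → 2× max-pool, then a 1×1×1 convolution block and global
  average pooling. Channel widths are (32, 64, 128, 64, 32), so the feature
  has length 32 and a 112-voxel edge traces 112 → 56 → 28 → 14 → 7. Local
  kernels and max-pooling bias this branch toward rapidly varying detail.
* **MLFE — meta-low-frequency encoder.** A 3D vision-transformer branch:
  non-overlapping patch embedding by a convolution with kernel = stride =
  patch size (default 16, giving 343 tokens at 112³), a learnable cls token,
  learnable randomly initialized positional encodings on all tokens, and six
  post-norm transformer encoder layers with 4 heads at d_model = 512. The
  final cls representation is the low-frequency feature. Self-attention
  aggregates globally, biasing this branch toward slowly varying structure.
* **FC-MLP.** The fMRI functional-connectivity matrix (116×116 Pearson
  correlations of AAL-region time series) is vectorized to its strictly
  upper triangle (6670 values — the matrix is symmetric with unit diagonal,
  so the full matrix is redundant) and passed through a three-layer
  perceptron (hidden width 256, ReLU + 20 % dropout after the first two
  layers) ending in one logit.

Both volumes (gray-matter sMRI and the DTI fractional-anisotropy map) pass
through the *same* MHFE and MLFE instances: they are meta-encoders applied
per modality. Implementation-wise the two volumes are stacked along the
batch axis, so BatchNorm statistics pool over modalities.

**Cross-fusion.** The four volume features — s_high, s_low, f_high, f_low —
are fused in all C(4,2) = 6 unordered pairs by concatenation, each pair
feeding an independent linear head that emits one logit. Pair order is
fixed: (s_high, f_high) is the high–high fusion, (s_low, f_low) the
low–low, and the remaining four are the high–low fusions within and across
modalities. "Six features from three fusion methods" admits exactly this
reading with six logits. With the FC-MLP logit appended, a sigmoid gives
seven probabilities.

**Voting.** Each probability is compared to a threshold (default 0.5; the
comparison is strict, so a probability exactly at the threshold votes
negative) and the subject is classified MDD iff strictly more than half the
votes are positive. With seven voters ties are impossible; ablations with an
even voter count break ties toward HC (the conservative call). Because the
vote is discrete, the continuous score used for AUC is the mean of the
active heads' probabilities.

## Training protocol

Binary cross-entropy averaged over the seven heads (every weak learner is
trained toward the label), Adam with learning rate 9e-4 and L2 weight decay
1e-8, batch size 4, 200 epochs by default. Evaluation uses either a single
shuffled 3:1 train/test split (116 subjects → 87/29) or 4-fold
cross-validation with near-equal shuffled folds, reported as mean ± SD over
folds. Weight initialization, shuffling and dropout all derive from one
integer seed; repeated runs with the same seed are bit-identical.

The network stack (3D convolution via im2col, batch normalization,
max-pooling, multi-head attention, layer norm, dropout, Adam) is implemented
in NumPy with explicit reverse-mode gradients, in float32; every layer's
backward pass is verified against central finite differences in the test
suite.

## Synthetic cohorts

No public data accompany the clinical cohort this design targets, so the
`cohort_sim` module generates cohorts whose *shapes* mirror it (default 54
MDD + 62 HC; volumes 112³ after nearest-neighbor resampling; FC 116×116)
and whose class signal is decomposed by construction:

* a shared smooth "anatomy" background per modality (Gaussian-filtered white
  noise, length-scale `smoothness`, unit variance);
* **low-frequency effect** — a fixed smooth unit-variance field added with
  amplitude `low_effect` to MDD volumes only;
* **high-frequency effect** — a fixed alternating-sign (±1) voxel texture
  inside a centered cube of edge D/2 (≈ 1/8 of the volume), amplitude
  `high_effect`, MDD only;
* **connectivity effect** — ROI time series follow a latent-factor model
  (every ROI loads 0.5 on a global factor; the first quarter of ROIs load
  0.2 on a block factor, raised by `fc_effect` for MDD), and the FC matrix
  is always the Pearson matrix of those series, so symmetry and unit
  diagonal hold by construction;
* i.i.d. Gaussian voxel noise (`noise_sd`) everywhere.

With all effects zero the classes are identically distributed — the test
suite verifies the voxelwise two-sample t-test rejects at the nominal 5 %
rate. Effect amplitudes have no empirical anchor; the tiny-profile defaults
(low 2.0, high 2.0, fc 0.8, noise 1.0) are chosen so that a short CPU
training run separates the classes cleanly. What the generator does *not*
emulate: brain anatomy, partial-volume structure, BOLD hemodynamics, spatial
noise correlation, site effects. Passing tests therefore demonstrate that
the pipeline recovers planted, well-posed signal — not clinical performance.

## Problem sizes used in tests

The full 112³ / 116-ROI geometry is exercised in forward-only shape checks.
Training-based checks use a reduced profile chosen for CPU-scale runs: 16³
volumes (the edge must be divisible by 2⁴ for the four poolings; 16 is the
smallest such edge), patch size 8, d_model 64 with 2 transformer layers,
16 ROIs, 64 subjects (32/32), 15 epochs. The same architecture family and
training protocol apply at both scales.

## Confusion-matrix arithmetic and table reconstruction

`metrics` evaluates ACC, PREC, REC, SPE exactly (rational arithmetic), F1 as
2TP/(2TP+FP+FN) (algebraically identical to the harmonic form on exact
values) and MCC in its covariance form. Metrics with zero denominators are
defined as 0 and flagged rather than raised, so degenerate ablation rows
still tabulate. AUC is the Mann–Whitney statistic computed by midrank
summation (identical to the trapezoid ROC area, with an explicit tie
contract).

`solve_confusion` inverts printed metric rows: it enumerates all O(n³)
non-negative integer quadruples (TP, FN, FP, TN) summing to the test-set
size and keeps those whose exact ACC/PREC/REC/SPE round (half away from
zero) to the printed three-decimal values. A unique survivor pins down the
row's confusion matrix, from which F1 and MCC follow exactly; zero or
multiple survivors are reported as inconsistent or ambiguous. This is how
the published ablation rows are validated end-to-end.

## Numerical and design choices

* **Nearest-neighbor resampling** uses the floor index contract
  i_src = ⌊i_out · src/target⌋ per axis, implemented directly on array
  indices (resampler dialects differ at boundaries; this one is documented
  and tested against a brute-force oracle). Only voxel coordinates are used;
  NIfTI affines pass through untouched.
* **Normalization** is per-volume min–max with ε = 1e-9 in the denominator,
  (x − min)/(max − min + 1e-9), mapping constant volumes to zeros and any
  volume into [0, 1). Order: resample, then normalize. A per-dataset or
  z-score alternative can be had by passing `normalize=False` and scaling
  externally.
* **Transformer feed-forward width** defaults to 2·d_model (lightweight
  choice) and the transformer itself runs without dropout; the 20 % dropout
  applies to the FC-MLP, where it is specified.
* **Patch size 16** at 112³ gives 343 tokens — large enough to matter,
  small enough to be tractable; configurable.
* **Probability clamp** at 1e-7 in the BCE loss; training aborts with the
  epoch index if the loss turns non-finite.
* **Checkpoints** are .npz archives of all parameters and BatchNorm running
  statistics plus a JSON config and version tag; save → load → evaluate is
  bit-identical.

## How robust is the frequency-specialization check?

The sanity check "a classifier trained on the MHFE branch wins when only the
high-frequency texture is planted, and one trained on the MLFE branch wins
when only the smooth field is planted" deserves a caveat. The high-frequency
direction is robust (seed-averaged margins of 0.2–0.3 in test accuracy at
texture amplitude 0.5). The low-frequency direction holds at the pinned
seeds used in the tests (MLFE 0.854 vs MHFE 0.729 mean accuracy over three
seeds at field amplitude 0.35) but is seed-sensitive: the convolutional
branch's receptive field is global after four poolings plus global average
pooling, so nothing structurally stops it from learning smooth fields, and
under other seed sets or harness variants it can match or beat the
transformer branch. Design-phase experiments across amplitudes 0.12–2.0 and
5–30 epochs found the direction reversed as often as not. A related
structural hypothesis — that the patch embedding attenuates balanced
textures relative to smooth fields — was tested and refuted: a randomly
initialized linear patch embedding is frequency-blind (random projections
preserve norms), so the ViT's low-pass character comes from token mixing in
attention, not the embedding. Treat the low-band comparison as a pinned
regression check, not as a stable property of the architecture pair.

## Known limitations

* The NumPy stack is single-threaded BLAS-bound; paper-scale (112³)
  training is out of reach on CPU, and only forward shape contracts are
  exercised at that size.
* Per-volume min–max normalization converts a purely local intensity effect
  into a small global rescaling (it shifts the volume max), which mildly
  couples the frequency channels; the specialization probes therefore run
  on raw volumes.
* The ablation harness restricts *voters* of one trained full model rather
  than retraining per modality subset; with private data the published rows
  cannot be reproduced either way, and the harness is validated on
  synthetic cohorts only.
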