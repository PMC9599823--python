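# Methods

## The decoding problem

A subject views images from one of ten categories while being scanned;
each stimulus block yields three whole-brain EPI volumes (TR 3 s) on a
64 x 64 grid of 50 axial slices. The decoder predicts the viewed category
from those three volumes. The design assumptions are:

1. Only visually responsive cortex is informative. Eleven regions of
   interest (ROIs) — V1d, V1v, V2d, V2v, V3d, V3v, V4, LOC, FFA, PPA and
   HVC, where HVC is the voxel-wise union of LOC, FFA and PPA — are given
   as binary masks on the acquisition grid; everything else is discarded
   by masking.
2. Spatial/temporal pattern within an ROI carries category information.
   Each ROI is processed by its own 3D convolutional stream over the
   masked volume, with the three time frames as input channels.
3. Between-ROI functional relations carry category information too. The
   eleven per-ROI feature vectors become node features of a graph whose
   edges are functional-connectivity weights, and a residual graph
   convolutional network (GCN) fuses them before classification.

## Per-ROI 3D-CNN streams

Each stream has nine layers in the main structure: six valid (no padding,
stride 1) convolutions with kernels 3x5x5 (C1–C5) and 3x3x3 (C6), each
followed by batch normalization and ReLU, interleaved with three
overlapping max-pools (kernel 3x3x3, stride 2x2x2) after every second
convolution. Channel counts are 16, 16, 32, 64, 64, 8. Per axis, each
layer maps extent `I` to `floor((I + 2P − D(K−1) − 1)/S + 1)` with P = 0
and D = 1 throughout. Iterating this over the schedule from (50, 64, 64)
gives

    depth : 50 48 46 22 20 18 8 6 4 1
    h, w  : 64 60 56 27 23 19 9 5 3 1

so the final activation is 8 channels on a 1x1x1 grid and the 8-element
feature vector is simply the flattened output — no pooling-to-vector or
dense head is needed or added. The kernel axis pairing (3 along the
50-slice depth axis, 5x5 in-plane) is forced: it is the only pairing under
which the schedule collapses to 1x1x1. `shape_chain` computes this algebra
in closed form and refuses infeasible configurations before any training.

The eleven streams share an architecture but not weights (a
`shared_weights` flag enables the tied variant). Initialization is a
seeded uniform fan-in scheme, U(±1/sqrt(fan_in)). Depth (6–11 layers) and
feature width (2–12) are exposed as configuration sweeps; the 9-layer
schedule is the canonical one, and the 10- and 11-layer presets are this
package's own instantiations and need anisotropic late kernels (e.g.
1x5x5, 1x1x1) to remain feasible on the full grid — uniform 3x3x3 pooling
a fourth time would collapse the depth axis below the pool kernel.

## Functional-connectivity graph

Edge weights follow a group-weighted Pearson rule: ROIs split into a
low-level group (V1d…V3v) and a mid/high-level group (V4, LOC, FFA, PPA,
HVC), and

    a_ij = omega * P(r_i, r_j)   same group (omega = 3 by default),
    a_ij = 1     * P(r_i, r_j)   across groups,
    a_ii = 0.

Two choices here are deliberate design decisions of this package:

* **What signal P is computed over.** Three frames per scan are too few
  for a meaningful correlation, so P is computed over ROI-mean time
  courses concatenated across all *training-subject* scans, once per
  experiment, and the adjacency is then frozen for training and
  inference. Using test subjects would leak held-out data into the model.
* **Negative correlations.** The propagation rule needs D̃^(−1/2) with
  D̃ the degree matrix of A + I; negative degrees have no real square
  root. We therefore use |P| by default (`signed=True` disables this),
  which also guarantees normalizability for any input.

The GCN consumes the symmetric normalization
Â = D̃^(−1/2)(A + I)D̃^(−1/2); for nonnegative A its spectrum lies in
[−1, 1]. `plain_pearson` (omega = 1) and `random` adjacencies are provided
as ablation baselines, and omega is sweepable over
{1.5, 2.0, 2.5, 3.0, 3.5, 4.0}.

## Residual GCN classifier

Five blocks of dropout(0.5) → graph convolution (H → ÂHW) → batch norm →
ReLU, with node-feature width 8 held constant so identity skips always
type-check, then a single dense layer over the flattened 11 x 8 features
producing 10 unnormalized scores (softmax lives in the loss). Batch-norm
statistics are per feature column, across nodes and batch.

Residual wiring, with Z = BN(Â · dropout(H) · W):

    A:    ReLU(Z) + H
    B:    ReLU(Z + H)        — the default (pre-activation addition)
    C:    ReLU(Z + H·Proj)   — Proj trainable, initialized to identity
    none: ReLU(Z)            — the no-residual ablation

Residual wiring admits several topologies; A/B/C above are this
package's explicit definitions. C keeps a
trainable projection even at equal widths (otherwise it would coincide
with B). The motivation for skips is over-smoothing: stacking graph
convolutions contracts node features toward a common value; a probe test
confirms that an 8-block no-skip stack shows lower inter-node feature
variance than the same stack with type-B skips.

## Training and evaluation

All eleven streams and the GCN train jointly: one Adam optimizer
(learning rate 0.01, weight decay 0.001 as classic L2, batch size 16,
200 epochs by default — scaled runs override only the epoch count) driven
by softmax cross-entropy, with gradients flowing from the scores through
the GCN into every stream in one backward pass. Splits are by subject —
3 train / 1 validation / 1 test — rotated deterministically over five
trials; labels never influence splits. The best checkpoint (parameters
*and* batch-norm running moments) is selected on validation loss; early
stopping is not used. Per-subject z-scoring (each subject's global mean
and SD over all its scans and frames) removes between-subject signal-level
differences; it uses no cross-subject statistics, so applying it to a
held-out subject leaks nothing. Min–max scaling is available as an
alternative normalization.

Evaluation derives per-class one-vs-rest TP/FP/TN/FN counts from the
multi-class confusion matrix and reports precision, recall, F-score
(beta = 1) and per-class accuracy by the standard formulas, macro
(unweighted) averages, and total accuracy = #correct/n. Zero-denominator
precision/recall is reported as 0 and flagged, so averages stay defined.
Argmax ties break toward the lowest class index.

## Numerical engine

No deep-learning framework is used: layers (valid 3D convolution via
im2col + BLAS matmul, overlapping max-pool with argmax scatter, batch
norm, inverted dropout, dense, graph convolution) carry hand-written
backward passes, verified in the test suite by brute-force oracles and
finite differences. Convolution caches its column matrix during training
so the backward pass is two matmuls plus a col2im scatter; the first
layer of each stream skips its input gradient (the input is data).
Training runs in float32; parameters and all closed-form/oracle paths are
float64. Everything stochastic draws from `numpy.random.Generator`
instances fanned out deterministically from one experiment seed
(`SeedSequence` spawn keys), so loss histories and metrics reproduce
bit-identically on a given platform.

## Synthetic data: what it emulates, and what it does not

The generator stands in for the blocked visual-stimulation dataset:

* one 3-frame volume per (subject, class, repetition):
  `gain_s * (baseline + pattern_{c,r} * ramp_t) + noise`;
* `pattern_{c,r}` is a fixed seeded spatial map per class inside each base
  ROI — per-voxel amplitudes Normal(e·sigma, (e·sigma)^2) with
  `e = effect_size` (default 2), `sigma = noise_sd` (default 1) — so
  classes differ in spatial arrangement, not merely mean level;
* `ramp_t = (0.8, 1.0, 0.9)` emulates a hemodynamic rise and fall across
  the three frames (the frames otherwise act only as channels);
* `gain_s = exp(Normal(0, subject_gain_sd))`, default SD 0.1, emulates
  between-subject signal-level differences (the motivation for subject
  normalization);
* baseline 100 in arbitrary scanner units; i.i.d. Gaussian voxel noise.

Templates are carved as disjoint compact ellipsoids (one per base ROI,
100–600 voxels on the full grid, proportionally smaller but never below
conv-kernel scale on reduced grids) in disjoint sub-boxes of the grid;
HVC is the LOC ∪ FFA ∪ PPA union, duplicated deliberately — features are
extracted from overlapping regions independently.

Deliberately absent: hemodynamic-response convolution, physiological and
structured noise, motion, EPI distortion, anatomical variability between
subjects, and class structure learned from real stimuli. Consequently,
passing tests show that the pipeline recovers class structure *of the kind
it assumes* from noisy multi-subject volumes — not that it attains any
particular accuracy on real acquisitions.

## Scaled experiment sizes

Whole-pipeline experiments in the test suite run on a reduced
(10, 12, 12) grid with a 4-layer stream preset that mirrors the full
design (cascaded small-kernel convolutions, overlapping pool, 8-wide
collapsed head): 5 subjects x 10 classes x 20 scans/class/subject and 20
epochs for the held-out-subject recovery and permuted-label null; 6
scans/class/subject and 15 epochs for the paired ablation runs (GCN vs
no-GCN head; residual B vs none at 8 blocks). The full 64 x 64 x 50
architecture is exercised end to end (forward) wherever shapes and
feature extraction are asserted.

## Known limitations

* The engine is CPU/numpy; full-grid *training* at acquisition scale is
  out of its intended range (full-grid forward passes take seconds).
* Bit-identical reproducibility holds per platform/BLAS, not across them.
* The 10/11-layer sweep presets and residual wirings A/C are
  package-defined instantiations; conclusions about them are conclusions
  about these instantiations.
* The synthetic generator's class patterns are static maps; it cannot
  probe representational questions (e.g. which ROI carries which
  category), only pipeline correctness.
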