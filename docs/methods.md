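# Methods

## Model

A bag is one patient's tumor: K = 32 axial slices of a standardized
64×64×32 tumor cuboid at 1 mm isotropic resolution. Each slice is embedded
by a shared-weight convolutional backbone followed by global average
pooling, giving `H = {h_1, …, h_K}`, `h_k ∈ R^D`. A MIL pooling operator
reduces H to a bag representation `z`, and a fully connected layer with a
sigmoid produces the response probability. Only bag labels supervise
training (binary cross-entropy); instances are never labelled.

The three pooling operators:

- **max**: `z_d = max_k h_{k,d}`. Permutation-invariant, parameter-free,
  keeps only per-feature extremes.
- **conv**: `z = Σ_k u_k h_k`, a K×1 kernel shared across all D channels,
  no bias. Deliberately *not* permutation-invariant — the kernel indexes
  slice position — and therefore constructed for a fixed K (32).
- **attention**: `z = Σ_k a_k h_k` with
  `a_k = softmax_k(wᵀ tanh(V h_k))`, `V ∈ R^{L×D}`, `w ∈ R^L`. The softmax
  is computed with max-subtraction, so weight normalization (Σ a_k = 1)
  holds for raw score magnitudes far beyond floating-point exp range. `z`
  is a convex combination of the rows of H, hence bounded feature-wise by
  their min/max.

## Preprocessing

CT volumes arrive with heterogeneous slice thickness and pixel size. The
pipeline is: (1) trilinear resampling in physical coordinates to 1 mm
isotropic voxels, output extent `round(dim·spacing)` per axis; (2) a
64×64×32-voxel crop centred on the supplied tumor center — for even
extents the center voxel occupies index `extent/2`, i.e. the floor split
falls on the low side — padded with air (−1000 HU) where the cuboid
overhangs the scan; (3) per-slice intensity windowing to [−1000, 400] HU
(a lung-mass window spanning air background through soft-tissue tumor; the
window is configurable), linear mapping to [0, 1], bilinear resize to the
backbone input size with pixel-center alignment, replication of the
grayscale slice into three identical channels, and per-channel
standardization with the conventional natural-image statistics of
pretrained backbones (mean 0.485/0.456/0.406, sd 0.229/0.224/0.225).
Windowing and normalization ahead of a pretrained network admit several
conventions; these defaults are documented choices, all configurable in
`build_bag`.

## Backbones

Instance embedding is a pluggable contract (`dmil.backbone`): a builder
maps a `BackboneSpec` to a layer stack ending at convolutional feature
maps. Two builders ship in-repo:

- `vgg16`: the standard 13-convolution VGG16 feature stack (3×3 convs,
  2×2 max pools). On 224×224 inputs it yields 512-channel 7×7 maps, so a
  bag produces a 32×512×7×7 tensor and, after global average pooling, a
  32×512 embedding matrix. Weights are randomly initialized (He); trained
  weights can be saved/loaded as `.npz` + JSON sidecar.
- `tiny_test`: two stride-2 conv blocks (3→16→8 channels) on 32×32 inputs,
  giving (K, 8, 8, 8) maps. It exists to keep the full image-level
  pipeline trainable on one CPU in seconds, with the same contract as the
  large backbones.

Other named architectures (alexnet, resnet34, densenet, mobilenet_v2) are
registry entries awaiting a user-supplied builder via `register_backbone`.

All layers — conv (im2col + GEMM), ReLU, 2×2 max pool, the pooling heads
and the classifier — are NumPy modules with hand-derived reverse-mode
gradients (`dmil.nn`), verified against central finite differences in the
test suite. Backbone math runs in float32 for the large stacks and float64
elsewhere.

## Training

Defaults mirror the study configuration: Adam, learning rate 1e-5, batches
of 32 bags, 50 epochs, binary cross-entropy. "Batch size 32" is read as 32
*bags* per optimizer step, since the bag is the MIL sample unit; a bag's
instances always travel together. The checkpoint returned is the epoch
with the best validation AUC (last epoch when no validation set exists).
Early stopping, weight decay, augmentation and class weighting are
deliberately absent. Backbone weights train by default (`trainable_depth:
all`); `head_only` freezes them.

Initialization: conv weights He, attention `V` Xavier, attention `w` and
the classifier head zero. Zero-initializing `w` makes every bag start at
uniform attention (mean pooling) so the score network learns departures
from uniformity rather than inheriting an arbitrary random instance
ranking; the zero head makes untrained models score 0.5 and its first
update move along the class-mean difference. All randomness flows from one
top-level seed fanned out into named streams (split, initialization,
shuffling, synthesis), so runs are bit-reproducible.

### Stratified split

The 70:10:20 split uses a stratified largest-remainder rule: per-class
quotas `ratio·n_class` are rounded by largest remainder, then reconciled —
moving single bags between splits within the most-entitled class — until
the split totals equal the largest-remainder apportionment of the whole
cohort. On a 301-bag cohort with 163/138 classes this yields (211, 30, 60)
with per-class allocations (114, 16, 33) and (97, 14, 27). Assignment
within a class is a seeded permutation of the sorted bag ids, making the
split invariant to manifest row order.

## Evaluation

Positivity is `score ≥ cutoff` (closed on the left), with label 1
(response) the positive class; the convention is flippable because
published sensitivity/specificity pairs in this area sometimes follow the
opposite orientation. AUC is the trapezoidal ROC area, identical to the
Mann–Whitney statistic with half-credit ties. The AUC interval is DeLong's
variance estimator with a normal approximation, truncated to [0, 1]; a
percentile bootstrap (2000 resamples) is available. Operating points:
Youden's maximizer of sensitivity + specificity − 1 and the threshold
minimizing the Euclidean distance to (0, 1) in ROC space, ties broken
toward the lower threshold. Decision-curve analysis reports
`NB(p) = TP/N − (FP/N)·p/(1−p)` against treat-all
(`π − (1−π)·p/(1−p)`) and treat-none (0) on a 0.01–0.99 grid.

## Synthetic data

The generator provides the MIL structure the model assumes, at two levels.

**Image cohorts**: volumes of lung-like Gaussian noise (mean −700 HU, sd
30 HU) containing one ellipsoidal tumor (mean +30 HU, semi-axes 8–14 mm)
at a recorded, slightly jittered center. In positive bags,
`max(1, round(signal_fraction·32))` randomly chosen tumor slices (capped
at the slices the tumor actually spans inside the cuboid) receive an
additive textured signal of mean magnitude `signal_effect` (default
150 HU = 5× the noise sd) inside the tumor cross-section. Negative bags
receive none. Injecting signal per-slice rather than globally gives
attention weights a ground-truth localization target. Defaults: 200 bags,
prevalence 0.5, 80×80×40 volumes at 1 mm.

**Embedding cohorts**: the same bag structure directly in feature space —
negative instances standard normal, signal instances shifted by
`signal_effect` standard deviations along one random unit direction drawn
per cohort. These bypass imaging for fast pooling/training tests.

What the generator does *not* emulate: anatomy (airways, vessels, pleura),
scanner physics (reconstruction kernels, beam hardening, dose noise
structure), tumor heterogeneity and margins, or annotation noise in the
tumor center. Passing tests therefore demonstrate that the architecture,
optimization and evaluation machinery behave correctly under the MIL
assumption — not that the model attains clinical performance; the study's
clinical cohorts are private, and their headline metrics are not
reproduction targets here.

## Problem sizes and numerical choices

The end-to-end experiment in the acceptance tests uses 200 image-level
bags with the `tiny_test` backbone, attention pooling and the default
hyperparameters at 20 epochs — a deliberate scale-down that keeps the full
simulate→preprocess→train→evaluate loop to about half a minute per run
while preserving every structural property of the full-size model.
Interpolation is trilinear (volumes) and bilinear (slices) with border
clamping; max-pool gradient ties resolve to the first maximum; the
attention softmax subtracts its max score; BCE is computed in the
logit-stable form. Degenerate metric denominators (empty classes at a
cutoff) yield 0 with a warning rather than NaN.

## Limitations

- No pretrained weights ship with the package; the VGG16-style backbone is
  randomly initialized unless a checkpoint is supplied, so transfer
  learning from natural images is an integration point, not a feature.
- Conv pooling is bound to the construction-time bag size; max and
  attention pooling accept any K ≥ 1.
- Gated or multi-head attention, instance-level pseudo-labelling,
  cross-validation and hyperparameter search are out of scope.
- Training is single-process CPU NumPy: suitable for the test-scale
  backbones; a framework-backed backbone would be needed for full-size
  fine-tuning at practical speed.
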