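# Methods

## Problem and model

The package classifies RGB photographs of human skin burns by depth —
superficial, deep dermal, full thickness — and by the derived clinical
decision graft / non-graft (graft = deep dermal or full thickness, the
depths that need skin replacement).  The classifier, BuRnGANeXt50, is a
slimmed ResNeXt-50: a 50-layer residual network whose bottleneck blocks use
grouped 3x3 convolutions with cardinality (number of parallel
transformation paths) C = 32, so each block computes an aggregated
transform `x + sum_i Y_i(x)` over C low-dimensional embeddings.  Relative
to the original ResNeXt-50 topology, the stem filter shrinks from 7x7 to
5x5 (while widening to 256 channels) and every bottleneck stage is
narrowed: stage widths (32, 64, 256, 512) expanding to (128, 256, 512,
1024) instead of (128, 256, 512, 1024) expanding to (256, 512, 1024,
2048).  Counting only the tabulated stage convolutions, the slim topology
has 4,898,912 trainable weights (5 x 10^6 to the nearest million) versus
22,911,680 (23 x 10^6) for the original backbone including its projection
shortcuts.  Despite the "GAN" letters in the inherited model name there is
no adversarial component anywhere in the architecture; none is implemented.

Leaky ReLU (slope 0.01, configurable) follows every convolution.  The head
is global average pooling, flatten, and a k-way softmax (k = 3 for depth,
k = 2 for graft).  Local response normalization — divisive normalization
over a sliding channel window, defaults t = 2, alpha = 1e-4, beta = 0.75,
n = 5 (the canonical AlexNet constants; the architecture description leaves
them unspecified) — is applied after the stem convolution and after the
conv2 stage, a configurable list.

## Attention

One attention block follows each bottleneck stage (conv2..conv5,
configurable).  Inside a block the C stage channels are channel-shuffled by
the (N, S) transpose-interleave permutation and split into N = 4 groups of
C/N channels, each divided into S = 4 subgroups.  S is fixed at 4 because
the subgroup transform is rotation by r quarter-turns with r = s; on the
discrete grid the rotation is standard array 90-degree rotation semantics
(transpose + flip), the exact recentred form of the continuous rotation
matrix.  A single 3x3 convolution K, shared across subgroups and groups,
maps each rotated subgroup; subgroups s > 0 are gated by the unrotated
response (Hadamard product with y0) and the results concatenated.

Channel attention is squeeze-excitation style: spatial global average
pooling per group, a shared two-layer fully connected map (bottleneck ratio
16, the standard squeeze-excitation default) with ReLU then sigmoid, giving
per-channel gates in (0, 1).  The gated groups are *summed*, so the
channel-attended map has C/N channels.  Spatial attention stacks the
channel-wise average and max maps into a 2 x H x W descriptor (an
elementwise-sum variant is available behind the `variant: sum` flag),
reduces it with a 3x3 convolution, and gates every position through a
sigmoid.  Because the groupwise sum leaves C/N channels, the block output
is restored to C channels by a learned 1x1 convolution and added residually
to the block input; this is the package's choice for integrating the
attention path at full stage width while preserving the groupwise-sum
semantics.

## Numerical conventions

* Padding: "same" padding with ceil-mode downsampling everywhere, so a
  stride-2 stage maps spatial size H to ceil(H/2).  This keeps the
  100 -> 50 -> 25 -> 13 -> 7 -> 4 trace well defined; `derive_shapes`
  recomputes it from the config by pure arithmetic and the forward pass is
  audited against it.
* Downsampling: spatial stride 2 on the 3x3 convolution of the first block
  of conv3/conv4/conv5 (the ResNeXt standard); the stem convolution and its
  3x3 max pool are each stride 2.
* Shortcuts: identity when input and output widths agree and stride is 1,
  otherwise a 1x1 projection with batch normalization.
* Batch normalization follows every convolution (the network does not train
  reliably without it) but is excluded from the `stage_tabulation`
  parameter convention, which counts only the tabulated convolutions; the
  `full_backbone` convention adds projection shortcuts, and `all` counts
  every trainable scalar including attention and the head.
* Activations sit after each convolution's batch norm and *not* after the
  residual addition, so a bottleneck whose three convolution weights are
  zero is exactly the identity map.
* Softmax is computed with max-subtraction; cross-entropy clips
  probabilities at 1e-12.
* Weights use He fan-in initialization adjusted for the Leaky ReLU slope,
  drawn from a seeded generator: a model build is a pure function of
  (config, seed).

The engine is a small reverse-mode autodiff over numpy arrays (float32 by
default) with im2col-based convolutions; pointwise 1x1 convolutions run as
batched matmuls without materializing patches.  Gradients of every
primitive are verified against central differences in the test suite.

## Training protocol

Categorical cross-entropy on softmax outputs, Adam (SGD+momentum
selectable) at an initial learning rate of 1e-3, mini-batch 32, 100 epochs
by default; all are configurable.  Evaluation uses stratified fivefold
cross-validation:
per-class 80/20 partitions (stratification avoids empty-class validation
folds on small datasets), deterministic under a seed.  When augmentation is
enabled it expands the training split only — validation images are never
augmented copies of training images — and the policy is recorded in the run
log.

Metrics are one-vs-rest per class from the confusion matrix: accuracy
(TP+TN)/(TP+TN+FP+FN), precision TP/(TP+FP), recall = sensitivity
TP/(TP+FN), F1, and specificity TN/(TN+FP).  A `literal` mode
computes specificity as TN/(TP+TN) instead — an alternative definition
sometimes seen in clinical classification reports — preserved for
auditability.  Zero-denominator cells are reported as NaN
with an explicit undefined flag, never silently as zero.  Macro (unweighted)
averages aggregate classes; the overall (trace/total) accuracy is reported
alongside.  ROC curves and AUC are one-vs-rest per class.

## Synthetic data generator

Clinical burn photographs are not redistributable, so the generator
emulates the color semantics clinicians use to grade depth: superficial
lesions red / pale pink (uniform texture), deep dermal lesions blotchy
red-and-white patches, full-thickness lesions a white/brown rim with a
deep-red core.  Each 100x100 image is an elliptical lesion (axes drawn from
30-40 px, jittered center and orientation) over a beige skin-tone
background with per-image tone jitter, plus Gaussian pixel noise
(sd 8 by default) clipped to [0, 255].  The dataset is a pure function of
its config: the same seed reproduces every pixel.

What the generator does and does not emulate: the three classes are
separable by lesion color statistics — a nearest-mean-color classifier
reaches ≥ 95% on a default 600-image set — which is exactly the cue
clinical color grading relies on, but the images carry none of the
photographic nuisances of real burn data (lighting, perspective, occlusion,
skin-tone diversity, wound borders).  Passing the synthetic training
criterion therefore demonstrates that the architecture, training loop and
evaluation pipeline are correct end to end; it does not certify clinical
accuracy, and accuracy figures obtained on clinical burn databases with
full-scale training are out of scope at desk scale.

The four default augmentations are horizontal flip, vertical flip, and the
two 30-degree rotations; a six-transform set adds the two 90-degree
rotations.  Free-angle rotations use bilinear interpolation with
reflect-padding fill — a black-corner fill would leak a label-independent
cue.  Because a four-transform set only quintuples a dataset while small
clinical corpora are typically expanded far beyond that, oversampling with
randomized augmentation parameters is supported to reach arbitrary target
counts.

## Scaled problem sizes

The repository's acceptance experiment trains on 600 synthetic images
(200 per class) for 10 epochs with batch 32 on a stratified 80/20 split,
using a half-width model variant (width multiplier 0.5, cardinality 16 so
the grouped-conv widths stay divisible); the variant is recorded in the run
log.  These sizes are the package's own scaled-down study conditions — the
color-separable generator saturates well before full-scale training — and
both tasks are expected at >= 90% held-out accuracy there.

## Known limitations

* The attention modules capture local dependencies only; no non-local or
  transformer attention is included.
* The engine is CPU/numpy; it is sized for the scaled experiments above,
  not for full clinical training runs.
* `literal` specificity is reported for audit purposes only; the
  standard definition is the default everywhere.
* Cross-platform bit-identity of the generator holds at the integer-pixel
  level for identical numpy/scipy versions.
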