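# Methods

## Architecture and counting conventions

The balanced binary-tree CNN is described declaratively
(`btcnn.archspec.BTCNNSpec`): an input shape, broadening levels whose
group counts double (1, 2, 4, 8), a merge plan (pairwise elementwise
addition of sibling leaves, one convolution group per merged tensor,
channel concatenation), and a dense classifier head ending in softmax.
The published instance is `default_btcnn_spec()`.

Parameter counting follows the convention that every convolution
(spatial, depthwise, pointwise) carries a bias, and every batch
normalisation contributes two trainable parameters (scale γ, shift β)
and two non-trainable moving statistics per channel. These choices are
forced jointly by the published component totals (3,584 for the first
256-kernel group; 10,304 and 3,104 for the depthwise-separable groups;
4,688 for the 32→16 groups) and the non-trainable total of 4,224
(= 2 × 2,112 batch-normalised channels). Two printed numbers are
arithmetically inconsistent with the rest of the table they appear in:
the 128-kernel convolution groups are listed as 295,562 where the closed
form (and the grand total 1,434,957) requires 295,552, and the
broadening-part subtotal is given as 660,756 where the component rows
sum to 660,736. The calculators follow the arithmetic; the grand totals
and every other row reproduce exactly.

Average pooling uses window 2×2 with stride 2 and no padding, so odd
spatial sizes floor (25 → 12); this is forced by the published shape
trace. Both group flavours end in the pool, and the order within a group
is convolution (ReLU applied) → batch normalisation → pool. A shape that
would collapse to zero anywhere in the tree is a validation error.

## Executable network

No deep-learning framework is required: the network
(`btcnn.netcore`) is NumPy throughout. Convolutions are im2col
(`sliding_window_view` + matmul) with hand-written backward passes; the
depthwise stage contracts 3×3 windows per channel; batch normalisation
uses biased mini-batch statistics in training and exponentially smoothed
moving statistics (the non-trainable parameters) at inference; dropout is
inverted and active only in training, after its layer's activation.
Training is mini-batch Adam (β₁ 0.9, β₂ 0.999, ε 1e-7) on the
categorical cross-entropy, with per-epoch loss/accuracy accumulated over
the training batches. The protocol defaults follow the published setup:
learning rate 1e-4, 20 epochs, batch size 24. One integer seed drives
weight initialisation (glorot normal), shuffling and dropout; identical
seeds reproduce identical histories bit for bit.

The whole-network backward pass was verified against central-difference
numerical gradients in float64 (101/101 sampled parameters within 1e-3
relative error), and each layer individually to 1e-4.

Two parameters the protocol leaves unstated are declared here rather
than inferred: batch-norm ε defaults to 1e-3 and the moving-statistics
momentum to 0.9. The momentum matters at desk scale: with only a few
hundred optimiser steps, a 0.99 momentum leaves the moving statistics
far from the batch statistics and inference-mode predictions lag far
behind training accuracy; 0.9 converges within a typical small run.
Probabilities are clipped to [1e-12, 1] inside the cross-entropy since
the loss is undefined at zero.

## Preprocessing

The chain is fixed in the printed order — grayscale (luminance weights
0.299/0.587/0.114), Gaussian blur (3×3), CLAHE (clip 2, 8×8 tiles),
binary threshold at 45 (strictly-below becomes background) with 2
erosions and 2 dilations (3×3 rectangle), crop, resize to 200×200,
scale to [0, 1] — and the configuration deliberately cannot reorder it.
The blur σ defaults to the window-derived rule 0.3·((k−1)/2 − 1) + 0.8
(= 0.8 for 3×3) and is configurable (e.g. to 0.3). CLAHE is implemented
directly: per-tile 256-bin histograms clipped at `clip ×` the mean bin
height, excess redistributed uniformly, tile mappings `cdf·255/n`
blended bilinearly between the four surrounding tile centres (tiles
padded symmetrically when the image does not divide evenly). With one
tile and a non-binding clip this reduces to global histogram
equalisation, which anchors the unit tests.

The crop box is the bounding box of the largest connected component of
the cleaned mask — standard practice for skull-region extraction — and
is applied to the CLAHE-enhanced image, not to the mask; an empty mask
falls back to the full frame. Erosion/dilation counts are configurable
because only "a series" of them is specified anywhere.

## Synthetic phantoms

`btcnn.synthetic_data` emulates the directory-per-class corpus layout
with 256×256 grayscale phantoms: a bright elliptical skull ring
(intensity ≈ 195–215) with jittered centre and axes, textured brain
tissue inside (≈ 85), near-black background (12) and additive Gaussian
noise (σ = 4, kept with the background safely below the threshold of 45
so the skull drives the crop). Lesion geometry, not mean intensity,
separates the classes: glioma is an irregular harmonic-perturbed blob
anywhere in the brain, meningioma a bright ellipse attached to the inner
skull rim, pituitary a small disk at the central brain base, and
no-tumour has no lesion. A leave-one-out nearest-centroid check on
downsampled images certifies each generated set is learnable (≈ 0.9 for
the defaults, chance when lesions are disabled).

What the phantoms do **not** emulate: MRI acquisition physics, bias
fields, anatomy, inter-subject variability, or the class-imbalance and
scanner heterogeneity of real corpora. Passing the pipeline on phantoms
demonstrates that the architecture, preprocessing and harness are
correct and that the network can learn spatial class structure — it
says nothing about accuracy on real brain MRI.

## Evaluation harness

Folds are stratified by default (protecting per-class counts) with a
fixed seed; `kfold_split` produces near-equal folds (7,022 examples →
1405/1405/1404/1404/1404). Metrics come from the confusion matrix:
per-class one-vs-rest precision/recall/F1, macro (unweighted) averages,
accuracy = trace/total, with zero-denominator metrics reported as 0 and
flagged. Cross-fold aggregation uses the arithmetic mean and the
*sample* (n−1) standard deviation — the published fold accuracies
{95.8, 95.09, 97.01, 96.01, 96.37} yield sd ≈ 0.709 under the sample
form, matching the printed value, versus ≈ 0.63 under the population
form. Each fold reports both held-out-fold metrics and whole-dataset
confusion counts, since the published per-fold correct-classification
counts approach full-dataset class sizes and therefore appear to use the
latter basis; neither is claimed to be the "test accuracy" basis.

## Problem sizes and design choices at desk scale

The test suite and examples run the full pipeline on 30 phantoms per
class with a small tree variant (32×32×1 input, 8-kernel conv level,
two 8-kernel depthwise-separable leaves, 8-kernel merge, 32-unit dense
layer with dropout 0.2, 4-way softmax) trained for 20 epochs at learning
rate 3e-3; preprocessed 200×200 phantoms are bilinearly downsampled to
the variant's input size. This configuration cross-validates to ≈ 0.97
mean held-out accuracy in seconds on one CPU and overfits a 48-image
subset to ≥ 0.95 training accuracy, which is what the end-to-end checks
assert. The full 200×200 architecture is built and forward-checked
(probability rows, shape trace, exact parameter tally) but not trained
in the tests; its published real-data accuracies would require the
combined multi-thousand-image MRI corpus and correspondingly long
training, which is outside this package's scope.

## Known limitations

* The NumPy trainer is single-threaded per BLAS and meant for small
  studies, not GPU-scale corpora.
* CLAHE matches the standard algorithm but is not guaranteed
  bit-identical to any particular library's implementation (interpolation
  at borders and histogram clipping conventions differ between
  libraries).
* The tree builder supports the level-doubling topology with uniform
  kernels per level and a single pairwise merge stage; arbitrary
  non-binary topologies are out of scope.
* Batch-norm momentum/ε and the blur σ are declared defaults, not
  published values.
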