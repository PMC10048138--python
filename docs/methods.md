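# Methods

This note documents the models, the synthetic data, the numerical choices
and the limits of what the test suite demonstrates.

## Problem

Short-axis late-gadolinium-enhancement (LGE) cardiac MRI shows infarcted
myocardium as hyperintense scar. The package segments each slice into four
classes — background (0), blood pool (1), myocardium (2), LGE (3) — with a
fully convolutional encoder/context/decoder network. Microvascular
obstruction (MVO), a dark core inside scar, is folded into the LGE class on
input (mask code 4 → 3): MVO is rare enough that it cannot sustain its own
class.

## Architecture

Three variants share one layout and differ only in the encoder:

* **MI-ResNet18-AC / MI-ResNet50-AC** — residual encoders. Blocks compute
  `R = relu(H(x) + shortcut(x))`; the 18-layer variant uses two-convolution
  basic blocks, the 50-layer variant 1×1/3×3/1×1 bottlenecks (expansion 4).
  Removing the shortcut recovers the plain cascade `R = H(x)` of a
  conventional CNN, which is exactly what the residual structure improves on.
* **MI-MobileNet-AC** — a MobileNetV2 encoder built from inverted residual
  bottlenecks: 1×1 expansion with ReLU6, 3×3 depthwise convolution, linear
  1×1 projection, additive skip only at stride 1 with matching channels.
  A width multiplier ε ∈ (0,1] uniformly thins every stage's channels
  (rounded, minimum 1); a resolution multiplier δ ∈ (0,1] shrinks the
  consumed input image. Both knobs are honoured for all encoders; for the
  residual family ε is a desk-scale convenience.

Every encoder exposes two taps: **low-level** features at 1/4 of the input
resolution (end of the stride-4 stage — standard encoder–decoder practice,
chosen to preserve fine boundaries) and **high-level** features at 1/16.
The final encoder stage trades its stride for dilation so the output stride
stays 16 and the context module sees a non-collapsed grid.

**ASPP.** Atrous convolution with rate k samples the input with gaps of
k−1 pixels, `h_i = Σ_n f_{i+k·n} w_n`, enlarging an n-tap kernel's
receptive field to n + (n−1)(k−1) at constant parameter count; k = 1 is
ordinary convolution. The pyramid runs four parallel branches on the
high-level features — 1×1, and 3×3 atrous at rates (k, 2k, 3k), each with
batch norm and ReLU — and fuses them. The base rate defaults to k = 6
(branch rates 6/12/18). Two open design points are resolved as follows:
fusion is channel concatenation followed by a 1×1 projection (concatenation
preserves per-rate information and matches the parallel-branch topology; a
sum would alias the scales), and no image-level pooling branch is added
because the design enumerates exactly four branches.

**Decoder.** ASPP output is up-sampled ×4 bilinearly, concatenated with a
1×1 projection (48 channels) of the low-level tap, refined by two 3×3
convolutions (256 channels), projected to per-class scores and up-sampled
×4 to input resolution. Decoder widths are unspecified upstream; 48/256
follow common encoder–decoder convention, and both are thinned by ε so that
desk-scale models stay small. Scores and features are interpolated
bilinearly; label masks always nearest-neighbour.

**DSC cost accounting.** The two-term multiply count of a depthwise
separable convolution is exposed as `dsc_cost(D_I, D_O, D_F, D_k, ε, δ)`.
The widely quoted two-term form omits the depthwise kernel factor D_k²;
because the depthwise filters here are 3×3, the function takes D_k
explicitly so both conventions are computable — `D_k=1` reproduces the
printed form, `D_k=3` the kernel-corrected count — and reports print both
rather than silently picking one.

## The numpy network engine

No deep-learning framework is part of the dependency set; the models run on
a small reverse-mode autodiff engine (`myinet.nn`) written on numpy:
strided/dilated/grouped conv2d via im2col with kernel-position slice loops,
batch normalisation (batch statistics in training, running in inference,
momentum 0.1), max pooling, dense-matrix bilinear resampling, ReLU/ReLU6,
concatenation, and a fused class-weighted softmax cross-entropy. All arrays
are float64. Every gradient is hand-derived and checked against central
finite differences in the test suite (conv/BN/pool/resize/loss, tolerances
1e-5…1e-6 absolute). Initialisation is He fan-in for convolutions,
unit scale/zero shift for batch norm, all drawn from one integer seed
through numpy `SeedSequence` spawning, so model construction, shuffling and
augmentation are exactly reproducible.

## Class weighting

With pixel frequencies F_i (ΣF_i = 1), median-frequency balancing sets
W_i = median(F)/F_i. For four classes the median is the mean of the two
middle order statistics, which forces the harmonic mean of the two weights
straddling the median to equal 1 — a self-check any such weight vector must
pass (the published 4-class vector does, to its printed precision; and for
the identity W_i·F_i = median(F), "exact" means exact up to the final
floating-point rounding of the divide and multiply). A zero frequency has
no finite weight; the function refuses it and tells the caller to drop or
floor the class. The loss is weighted softmax cross-entropy **averaged over
pixels, not over the weight sum**, so learning-rate semantics do not depend
on the weight scale. The mean pixel weight is then n·median(F) (≈0.4 for
the phantom's imbalance), which makes weighted gradients smaller than
unweighted ones — visible in the desk-scale results below.

## Synthetic phantom

The generator emulates the *structure* of clinical LGE-CMR, not its
physics: a blood-pool disk (radius 48–64 px at 256², scaled with image
size) inside a myocardial annulus (thickness 14–22 px), an angular scar
wedge (30–100°) on the endocardial side with transmurality 0.35–0.9,
optionally (p = 0.3) a dark MVO core that keeps the LGE label; a linear
background ramp (amplitude 0.08) and Gaussian pixel noise (sd 0.03).
Default tissue means — background 0.20, muscle 0.35, blood 0.70, LGE 0.75,
MVO core 0.25 — encode the two facts that make the clinical task hard:
nulled myocardium is dark, and scar is nearly as bright as adjacent blood,
so intensity alone cannot separate LGE from blood pool. Labels are an exact
function of the sampled geometry (asserted in tests by regeneration), and
the pixel-count ordering background > blood > muscle > LGE holds for ≥95%
of seeds; LGE is ~1% of pixels.

Cohorts draw geometry and intensities once per patient, jitter them per
slice (narrowed parameter ranges), and assign splits per patient by
largest-remainder rounding of the 60/20/20 fractions, so no patient leaks
across splits. What the phantom does **not** model: MRI noise statistics
(Rician), coil shading beyond a linear ramp, papillary muscles, through-
plane effects, vendor differences, anatomical variability. Passing tests
therefore demonstrate correct mechanics and optimisation behaviour of the
pipeline, not clinical-grade performance.

## Training regimen

Momentum SGD (momentum 0.9 — conventional, unspecified upstream) on
shuffled mini-batches of 10; initial rate 1e-3; the printed drop "factor 3"
is implemented as multiply-by-1/3 every 10 epochs (a multiplicative factor
greater than one would *raise* the rate, contradicting "drop"); at most 50
epochs. Validation runs once per epoch; early stopping triggers after 4
consecutive validations without a strict decrease of the best validation
loss, and the returned parameters are those of the best validation epoch,
never the last. Geometric augmentation (uniform rotation in [0,360),
uniform scaling in [0.9,1.1], joint on image and mask, nearest-neighbour
for labels, background fill for exposed regions) is applied on the fly to
training batches only.

## Desk-scale protocol and what it shows

The reference experiment (`myinet.protocols.desk_scale_learning`, also run
by `scripts/acceptance.py`) trains a width-halved (ε = 0.5) MI-ResNet18-AC
on 60 phantom slices at 64×64 (20 patients × 3, split 48 train / 12
validation by patient) for ≤30 epochs under the regimen above, twice with
identical seeds: once unweighted, once with median-frequency weights. At
the frozen regression seed (11) the unweighted run reaches validation
global accuracy 0.916 but LGE recall 0.00 — the majority-class bias the
weighting exists to counter — while the weighted run reaches LGE recall
0.85 at global accuracy 0.73. The protocol sizes (image 64², 60 slices,
ε = 0.5) are the package's chosen desk-scale study conditions; global
accuracy is asserted on the unweighted run because plain cross-entropy is
the objective aligned with that metric, and the weighted run is asserted to
dominate on LGE recall. A separate capacity check overfits a single 64×64
phantom to ≥0.99 accuracy in 200 steps (lr 0.1; accuracy measured with the
fitting batch's own normalisation statistics, since that batch *is* the
dataset).

## Evaluation conventions

All aggregate metrics derive from the confusion matrix with **rows = true
class** (serialised matrices label the orientation; published tables of
this kind sometimes caption rows as predictions while their rows sum to one
over true classes — the row-normalised diagonal equals per-class recall
either way). Per-class IoU uses the standard union M_a + H_a − P_aa (the
printed index-mixed form M_a + H_b − P_aa is read as a typo for the verbal
definition); weighted IoU weights per-class IoU by true-pixel share; mean
accuracy skips classes absent from the ground truth (with a warning) and
reduces n. Boundary F1 extracts boundaries by 4-adjacency (image border
counts as outside), measures exact Euclidean distance transforms, applies a
strict `d < tol` test with tol defaulting to 0.75% of the image diagonal
(not rounded), and averages per-class F1 over classes present in either
mask, then image scores over images — never pixel-pooled, so every image
counts equally. A class absent from both masks is skipped, not scored 0
or 1.

One published inconsistency is documented rather than resolved: of the
three variants' published aggregate mean accuracies, only the 18-layer
variant's (0.8483) equals the mean of its per-class accuracies; the
implementation follows the defining formula literally.

## Known limitations

* The engine is CPU/numpy: fine at 64–256 px desk scale, not for
  full-scale clinical training.
* No pretrained weights; all training is from scratch.
* The phantom's simplicity means desk-scale accuracy figures say nothing
  about clinical accuracy; they are regression fixtures for the pipeline.
* `segment` breaks score ties toward the lowest class index — deterministic
  but arbitrary.
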