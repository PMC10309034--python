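# Methods

## The model

`stnet` implements a two-stream convolutional network for binary lesion
classification (malignant vs. benign) with auxiliary segmentation
supervision.  The design premise is that convolutional encoders pre-trained
on natural images are texture-biased and under-represent object geometry,
while some lesion classes are distinguished mainly by boundary shape.  The
network therefore learns two parallel representations of the same image and
fuses them:

* **Texture stream.**  A ResNet-style bottleneck encoder whose 1×1 / 3×3 /
  1×1 convolutions use *pyramid-grouped convolution* (PGC): group counts
  grow through the block from 1 (standard, dense channel connectivity) to
  the channel count (depth-wise), following the geometric schedule
  g_l = nearest divisor of C to C^((l−1)/(L−1)).  Divisor rounding uses
  log-space distance with ties broken toward the smaller divisor, and the
  schedule is clamped non-decreasing.  The pyramid interpolates between the
  dense and depth-wise extremes, trading parameters for sparser channel-wise
  receptive fields deeper in the block.
* **Shape stream.**  The same backbone geometry with the 3×3 convolutions of
  the deep stages replaced by deformable convolutions
  y(p) = Σ_k w(p_k)·x(p + p_k + Δp_k), where the per-location tap offsets
  Δp_k come from a zero-initialized standard convolution over the same
  input and fractional positions are read by bilinear interpolation
  (zero outside the array, matching the zero-padding convention; (row, col)
  coordinates, pixel centers at integers).  Zero initialization means the
  stream starts as an ordinary convolutional encoder.  A deconvolution
  decoder (×2 transposed convolutions followed by two-conv residual blocks,
  widths halving per stage, logistic output) predicts the lesion mask from
  the *deepest* feature map only — there are no encoder–decoder skip
  connections, so mask supervision must flow through the same feature map
  the classifier consumes.
* **Fusion.**  The shape feature passes a gradient-scaling layer (identity
  forward, gradient ×α backward), the two maps are concatenated, and a
  channel-attention gate selects channels: each channel is summarized by
  ½(mean + max) over space, two bias-free 1×1 transforms with logistic
  activations produce per-channel weights in (0,1), and the map is rescaled
  channel-wise.  Both nonlinearities are logistic — unusual (SE-style blocks
  rectify the hidden layer) but intentional, and it makes the gate an
  element-wise contraction.  Global average pooling and a single
  fully-connected layer with logistic output give the malignancy score p;
  a sample is called malignant when p > 0.5 (strictly).

## Objectives

Classification uses the asymmetric loss
L_CLS = −y(1−p)^{γ₊} ln p − (1−y)·p_t^{γ₋} ln(1−p) with
p_t = max(p − φ, 0); it reduces to binary cross-entropy at γ₊=γ₋=0, φ=0.
γ₊ < γ₋ damps the abundant negatives harder than the rare positives, and the
cutoff φ removes already-confident negatives entirely.  Defaults: γ₊ = 1,
γ₋ = 3 (the best-performing setting of the reference recipe), φ = 0.05 (kept
small so only near-certain negatives are discarded; no reference value
exists).  Probabilities are clamped to [1e−7, 1−1e−7]; logs are natural; the
focusing weights are differentiated through, as in focal-style losses.
Segmentation uses pixel-wise mean squared error between the predicted and
binary ground-truth masks, averaged over the mask-bearing samples of the
batch only; batches without any mask contribute no shape term.

Three parameter groups are optimized jointly from a single total loss
L_CLS + β·L_SHP: the texture encoder receives only the classification
gradient (the shape loss does not reach it), the decoder receives only
β·L_SHP, and the shape encoder receives α·∂L_CLS + β·∂L_SHP, with α realized
by the gradient-scaling layer on the shape-feature-to-fusion path.  Folding
β into the total loss rescales the decoder's effective learning rate by β
relative to a unit-weight decoder objective; the minimizer is unchanged for
any β > 0, and β = 0 switches joint learning off entirely (the decoder then
receives no signal).  Defaults α = 0.1, β = 1.0: no reference values exist,
so α is set small enough that segmentation supervision dominates the shape
encoder early, and both are exposed in the config (`alpha`, `beta`) together
with a γ₋ sweep harness for re-deriving good values.

## Numerical core

No deep-learning framework is used: the package carries its own reverse-mode
autodiff engine on numpy arrays (`stnet.nn`), with im2col/col2im grouped
convolution, transposed convolution, max pooling, batch normalization
composed from primitives, a deformable convolution with analytic gradients
for input, weights *and* offsets, and an RMSprop optimizer (momentum 0.9,
squared-gradient decay 0.99).  Gradient correctness of every primitive is
property-tested against central finite differences.  Arithmetic is float64;
weights use seeded He initialization; all forward passes are deterministic
given weights, and training is a pure function of the config seed (data
order, augmentation and initialization all derive from it).

Conventions worth noting: subgradient at the `max(·, 0)` kink routes to the
first argument; spatial max-pool gradients go to the first argmax;
precision/recall with zero denominators are defined as 0; p = 0.5 is
classified negative.

## Synthetic data

The generator emulates the statistical structure the method assumes rather
than the appearance of dermoscopy or pathology images:

* **Shape cue** — lesion boundary r(θ) = R(1 + irregularity · Σ seeded
  low-order sinusoids), harmonics of orders 2–8 with unit-RMS normalized
  amplitudes, radius floored at 0.1 R.  Star-shapedness guarantees a single
  connected component.  Benign irregularity ~ U(0, 0.15), malignant
  ~ U(0.25, 0.5): disjoint ranges, so a threshold on boundary radial
  variance alone separates the classes (verified at accuracy > 0.9 on 200
  samples).
* **Texture cue** — Gaussian speckle inside the lesion with class-dependent
  standard deviation (benign U(0.02, 0.06), malignant U(0.10, 0.16) on the
  unit intensity scale), a smooth seeded background gradient outside.
* **Imbalance** — the default malignant:benign ratio in the experiments is
  ≈ 1:2.85 (e.g. 452/1287 at small scale).
* **Partial annotation** — a seeded `mask_fraction` (default 0.15, the
  annotated share of the reference dermoscopy corpus) of samples carry
  masks; masks are stored as {0,255} 8-bit PNGs binarized at >127 on load.

What the generator does **not** model: hair/ruler artifacts, color
variation, multi-scale cell morphology, annotation noise, or any
pathology-specific appearance.  Passing tests on this data demonstrate that
the mechanisms work as designed — not that the architecture reaches any
particular accuracy on real dermoscopy or histopathology images.

## Desk-scale experiments

All training experiments use the `tiny` profile: 2-stage stride-8 encoders
(final feature 8×8×64), 64×64 images, batch 8, a few dozen training images —
sized so a full comparison runs in minutes on one CPU.  The full-size
50/101-layer profiles (stride 32, 2048 final channels, 224×224 inputs) are
exercised as forward-pass geometry checks only; reproducing published
benchmark accuracies would require the real datasets, ImageNet pre-training
and GPU-scale training, and is out of scope.

* **Overfit capacity**: the tiny model reaches training accuracy 1.0 on 32
  synthetic samples within 200 steps.
* **Imbalance mechanism**: on 1:3 imbalanced data (30/90), asymmetric loss
  vs. cross-entropy, 3 seeds, 8 epochs; compared on malignant test recall.
* **Joint-learning mechanism**: texture cue neutralized (equal speckle
  ranges), every sample masked, 24/48 samples, 3 seeds, 30 epochs — long
  enough for the decoder to learn before it can teach the encoder; the β = 1
  and β = 0 runs are identical in every other respect (architecture, α,
  data, init), isolating the joint-learning term.  Compared on best
  validation F1.
* **Cross-validation**: stratified 5-fold on 60 samples, per-fold F1 spread.

Augmentation is random rotation in ±30° and random cropping to 87.5% with
resize back, applied identically to image and mask (magnitudes are package
choices; the reference recipe names the augmentations without magnitudes).

## Known limitations

* The numpy engine is single-threaded apart from BLAS matmul; the full-size
  profiles are usable for inference-style checks, not training.
* Batch-norm statistics make the training forward depend on batch
  composition; determinism holds for a fixed seed but not across batch-size
  changes.
* The directional experiments use three seeds; they establish direction
  under the stated conditions, not effect sizes.
* Decoder depth ("mirroring an 18-layer residual decoder") and the PGC
  schedule are package design choices where the underlying design space was
  genuinely open; both are config-overridable.
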