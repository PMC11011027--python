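# Methods

## Problem and model

The package addresses closed-world animal re-identification: every image
shows one individual, identity is encoded in the coat pattern, and the
task is to rank a gallery by descriptor similarity to a query. The model
is a serial dual-branch convolutional descriptor extractor trained as an
identity classifier; at inference the classifier is discarded and the
4096-d concatenated descriptor (full profile) is compared by Euclidean
distance.

Assumptions worth stating explicitly:

- **Single-pool protocol.** Query and gallery are the same image pool;
  the only exclusion is the query's own image (matched by image id).
  No camera-id or time-based filtering is applied. Queries with no
  same-identity gallery item are excluded from both mAP and CMC, with the
  excluded count reported.
- **Cross-entropy only.** Identity discrimination is learned purely from
  the classification objective; no metric-learning (triplet/circle) term.
- **Serial branches.** The local branch consumes the global branch's
  fused map (`P3 + C4`), not the raw backbone output, so part features
  see pyramid-fused texture.

## Architecture choices

- **Stem stride.** The stage geometry is specified relative to an input
  whose stage-1 map is 1/8 of the input size, one halving more than the
  textbook 50-layer design. The stem therefore contains an extra stride-2
  max-pool (flag `extra_stem_pool`, default on in both profiles); with it
  a 256×512 input yields C1 = 256×32×64 through C4 = 2048×8×16.
- **Last down-sampling removed** is implemented as stage-4 entry stride 1
  (including the projection shortcut), the standard re-ID practice; C3 and
  C4 share spatial size, which is what lets the deepest pyramid level use
  a stride-1 projection.
- **Pyramid fusion order** is add → 3×3 conv (+BN) → ReLU at every level.
  The level projections are learned stride-2 (stride-1 at the last level)
  3×3 convolutions with batch norm, because the channel count doubles
  between levels and a parameter-free pooling could not provide that.
- **Deep merge.** `P3` and `C4` are merged by elementwise sum before the
  global average pool, preserving the 2048-channel width; a
  `merge="concat_reduce"` variant (concat + 1×1 conv back to 2048) is
  available behind the same interface.
- **Local branch ordering.** Each block is max-pooled to 1×1 and reduced
  to 512 channels *before* the attention; at 1×1 spatial size the spatial
  gate degenerates to a single scalar. This pool-first ordering is the
  default; `pool_position="post"` runs the attention on the full-resolution
  reduced block and pools afterwards, for users who want a spatially
  meaningful gate. The four blocks share one set of reduction/attention
  weights (`shared_weights=False` to unshare); sharing keeps the parameter
  count low and makes the part operator translation-consistent.
- **Attention hyperparameters** follow the canonical CBAM settings:
  channel reduction 16, spatial kernel 7, channel gate before spatial
  gate, both sigmoid (so the module can only attenuate).
- **Classifier** is a single bias-enabled linear layer on the concatenated
  descriptor, initialised at σ = 0.01; feature-extractor convolutions are
  He-normal, batch-norm γ=1/β=0.

## Training schedule

SGD with momentum 0.9 and weight decay 5·10⁻⁴ on all parameters; base
learning rate 0.002, classifier group 0.02, both multiplied by 0.1 once
at epoch 100 of a 150-epoch schedule (`TrainConfig` holds these defaults;
short runs pass `epochs=` to `fit()` and stay on the pre-decay plateau).
Batch size 16. Augmentation applies to the training split only: per image
and per epoch, a coin flip (p = 0.5) for random rotation within ±15° and
an independent coin flip for random erasing of a rectangle covering
2–20% of the image. Batch-norm runs in batch-statistics mode during
training and uses running statistics (momentum 0.1) at evaluation; no
test-time augmentation. All randomness flows from `TrainConfig.seed`, so a
run is reproducible on one machine to the reproducibility of float32 BLAS.

## Numerical engine

The network runs on a small reverse-mode autodiff engine over float32
numpy arrays. Convolution is im2col + matmul with an analytic scatter-add
backward; batch normalisation implements the standard training-mode
gradient; max-pool backward routes gradients to argmax positions
(first-index tie-break, matching numpy's argmax). Softmax cross-entropy
is fused (probabilities computed in float64, log clamped at 1e-12). Every
backward pass is verified against central differences in the test suite;
composite checks avoid ReLU kinks so the finite-difference reference is
meaningful at step 1e-2.

## Synthetic benchmark

The generator emulates the structure of a coat-pattern re-ID corpus:

- **Identity** = a fixed texture parameter set: stripe frequency (4–12
  cycles per body length, spread by a golden-ratio low-discrepancy
  sequence that guarantees a minimum pairwise gap — measured ≥ 0.1 cycles
  over 50 identities), phase, stripe angle (±25°), jaggedness (fixed
  wobble harmonics) and a warm base tone.
- **Nuisance per image** = pose offset (±6% of canvas), scale (0.9–1.1),
  viewpoint rotation (±10°), procedural background clutter, sensor noise,
  and with p = 0.25 an occluding noise rectangle. The body ellipse and the
  stripes are evaluated analytically on the pixel grid, so nuisance
  transforms introduce no resampling artefacts.
- **Split**: per identity, images are split train:val at 0.7 (rounding
  half-up on the train side), guaranteeing every identity at least one
  training image.

The default desk-scale study uses 8 identities × 12 images at 64×128 and
30 training epochs — sized so the complete experiment (data, training,
evaluation) runs in about a minute on one CPU. A 1-NN classifier on
masked spectral features reaches 91% leave-one-out accuracy on a
10-identity × 10-image set, so the benchmark is learnable and a trained
network's retrieval quality is a meaningful signal.

What the benchmark does **not** emulate: articulated pose and body
deformation, illumination changes, multi-camera colour shifts, flank
asymmetry (left/right sides of a real animal differ), detection/cropping
noise, and class imbalance. Passing tests therefore demonstrate that the
architecture, objective, schedule and evaluation stack are wired
correctly and can learn pattern identity from images — not that the model
reaches any particular accuracy on real camera-trap data.

## Degenerate inputs and tie-breaks

- Distance ties in ranking are broken by gallery index (stable sort).
- A gallery that is empty after self-exclusion raises.
- `cross_entropy` clamps log arguments at 1e-12 and never returns NaN.
- Rotation by 0° and erasing with a degenerate area range are exact
  no-ops / exact-area rectangles where the canvas allows (the erased
  pixel count equals the drawn area fraction whenever an exact-area
  rectangle fits, e.g. 50 pixels on a 10×10 image at fraction 0.5).
- `pretrained=True` without an explicit weights file raises rather than
  silently falling back to random initialisation.

## Known limitations

- No GPU path; the full profile is forward-practical (seconds per image)
  but not training-practical. The desk profile is the supported training
  configuration.
- SENet/ECA-style alternative attention modules are not implemented; the
  attention interface is the CBAM composition only.
- No re-ranking post-processing (k-reciprocal etc.) and no cross-camera
  evaluation protocol.
- The classic top-down pyramid is deliberately absent from the model; the
  bottom-up (inverted) path is the design under test.
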