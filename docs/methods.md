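# Methods

## Problem and model

`dnlseg` segments thin curvilinear structures (blood vessels) in 2D medical
images with a U-shaped encoder–decoder whose distinctive parts are three
attention modules:

**Deformed non-local block (DNL).** A standard non-local block computes a
positional self-attention matrix of size (HW)×(HW),

    y_i = (1/C(x)) Σ_j f(x_i, x_j) g(x_j),

with f either the embedded-Gaussian similarity exp(θ(x_i)ᵀφ(x_j))
(softmax-normalised over j) or the dot product (normalised by N = HW); the
output carries a residual projection z = W_z y + x.  Its attention product
costs C̄·(HW)² multiply-accumulates, prohibitive at decoder resolutions.
The DNL block transposes the similarity to channel-against-channel,
producing a C̄×C̄ matrix and reducing the product to C̄²·HW MACs — exactly
HW/C̄ times fewer, which `fg_product_op_counts` certifies in rational
arithmetic.  The attended map is pooled by a learned 1×1 "pooling"
convolution into a C̄-wide descriptor, squeezed through a bottleneck of
width C̄/rate, expanded to a C-vector of channel weights that gates a
1×1-convolved copy of the input, passed through a squeeze-and-excitation
(SE) tail, and closed with a residual connection.

Numerical choices in DNL:

- The similarity is written once as exp(·) and once as softmax(·) in its
  two published forms; we apply a single softmax to the raw θφᵀ product
  (softmax already exponentiates), avoiding double exponentiation.
  Softmax is row-wise: each query channel's distribution over key channels.
- The descriptor bottleneck uses a ReLU between the reduce and expand maps
  (the SE convention) and, by default, a sigmoid on the final channel
  vector so the gate is bounded in (0,1); both the gate and all 1×1-conv
  biases are configurable.
- C̄ defaults to C (no bottleneck in θ/φ/g); rate defaults to 4 and the SE
  tail reduction to 16, clamped per block to the largest divisor of the
  local channel width so narrow test presets remain valid.

**Multi-scale feature fusion (MFF).** Each decoder stage fuses the deep
(coarse) feature x_deep with the encoder skip x_skip as

    MFF = AV(DNL(x_deep)) ⊙ x_skip + UP(x_deep),

where AV = gate(Conv₁ₓ₁(L2-normalise(GAP(·)))) is a channel-attention
vector broadcast over the skip map, and UP is bilinear 2× upsampling (a
nearest-neighbour and a transposed-convolution variant are configurable)
followed by a 1×1 projection that aligns channel counts — the published
description is silent on channel matching, so the projection is our
addition.  The L2 normalisation maps a zero vector to zero (implemented as
x/√(Σx²+1e−12), exact at zero and within 1e−12 elsewhere).  The published
prose swaps the meaning of the high/low subscripts relative to its figure;
we bind x_hig to the deeper decoder feature, consistent with standard
U-Net decoding.

**Residual SE pyramid pooling (RSEP).** The bottleneck applies four
parallel branches of 3×3 atrous convolution with dilations (1, 6, 12, 12),
each followed by SE, a 1×1 convolution and ReLU; the branch outputs are
concatenated with the original features (width C + 4·branch_channels) and
fused back to width C by a final 1×1 convolution, so the module is a
drop-in.  The duplicated dilation 12 is kept as published; a strictly
increasing (1, 6, 12, 18) preset is provided.  Branches are parallel (per
the published figure), not cascaded, and the original-feature concat uses
the post-ReLU branch outputs.  Oversized dilations on small maps trigger a
warning, not an error.

**Assembly.** Encoder stages are two (3×3 conv → BN → ReLU) layers with
channel width doubling from `base_width`, downsampled by 2×2 max-pool (the
downsampling operator is unstated in the source design; max-pool is the
U-Net convention).  Input spatial dims must be divisible by 2^n_stages.
The decoder applies DNL+MFF per stage followed by one 3×3 conv+BN+ReLU
refinement block (config-gated); the head is a 1×1 convolution with
sigmoid for binary vessel probability.  A softmax multi-class head is
deliberately out of scope.

## Training recipe

Adam with β₁ = 0.5, β₂ = 0.999, initial learning rate 1e−3, decayed per
epoch by (1 − (epoch−1)/total)^0.9 over a default of 200 epochs, batch
size 4.  The loss is `dice_w`·(1 − soft Dice) + `wce_w`·weighted BCE with
`dice_w = wce_w = 1` (the published combination does not state weights)
and the positive-class weight defaulting to the per-batch
background/foreground pixel ratio; probabilities are clamped at 1e−7.  The
Dice denominator uses squared sums (Σp² + Σq²) and an epsilon so the
empty/empty case yields loss 0.  Validation is a seeded 20% split; the
best-validation checkpoint is restored after training.  The poly schedule
is applied per epoch (the published formula is written in epochs).

Preprocessing for fundus-style inputs follows grayscale → per-image
standardisation → CLAHE → gamma, in that order; CLAHE operates on a
min-max rescaled copy because it is defined on [0,1] intensities.
Training patches (default 96×96) are cropped with centres uniform over the
full image, reflect-padding near borders so marginal vessels stay
sampleable.  CTA-style augmentation composes a random affine (±10% scale,
small shear), rotation (±15°) and a vertical flip, applied identically to
image and mask with nearest-neighbour mask resampling.

## Implementation substrate

No deep-learning framework is used: the layers, reverse-mode autodiff,
and the Adam optimizer live in `dnlseg.nn` on NumPy (float64).
Convolution is an im2col gather plus einsum contraction with a col2im
scatter-add backward; every primitive's gradient is finite-difference
tested.  This keeps runs bit-reproducible on one device from (config,
seed) alone.  Checkpoints are single `.npz` archives holding the weight
arrays, a JSON config snapshot and the build seed.

## Metrics and post-processing

SE = TP/(TP+FN), SP = TN/(FP+TN), ACC = (TP+TN)/N, soft-capable Dice, and
mean IoU averaged over {background, vessel} per-class IoU.  Undefined
ratios (e.g. an empty positive class) return NaN with a warning, never a
silent 0, and empty classes are excluded from the mean IoU with a warning.
ROC-AUC is computed on soft scores (scikit-learn's implementation, which
equals the Mann–Whitney statistic; the test-suite cross-checks it against
an exhaustive pairwise-comparison oracle).  Binarisation threshold
defaults to 0.5 and both soft and hard Dice are reported, since published
practice is ambiguous about which is meant.

The noise filter deletes connected components (8-connectivity by default)
smaller than 0.03% of the total foreground.  It operates per 2D slice
here; the original procedure applies it to a reconstructed 3D vasculature,
a documented divergence since 3D is out of scope.

## Synthetic phantoms: what they emulate and what they do not

Phantoms are unions of smooth random spline strokes (waypoints jittered
perpendicular to the chord by `tortuosity` × length) dilated to sampled
widths; the mask is the exact stroke union, and the image is a two-level
intensity map, Gaussian-blurred then corrupted with Gaussian noise.  Two
presets are shipped: a CTA-style slice (vessel 0.70 vs background 0.25,
noise σ 0.12, blur 0.9 — chosen so that a plain Otsu threshold visibly
degrades (Dice ≈ 0.6) while the structures remain learnable, emulating the
regime where learned smoothing pays) and a fundus-style 96×96 patch
(contrast 0.20, σ 0.03).  Foreground fraction is capped at 25%.

Phantoms emulate thin bright curvilinear foreground on a noisy background;
they do not emulate contrast inhomogeneity, anatomy-correlated background
texture, branching topology, or scanner artefacts.  Passing the learning
checks therefore demonstrates that the network, loss and optimizer can
extract curvilinear structure from noise — not clinical-grade performance
on real CTA or fundus data, which would require the original datasets and
GPU-scale training.

## Problem sizes used in the checks

The self-contained experiment trains the small preset (2 stages, base
width 8) on 128 phantoms of 64×64 for 30 epochs — about three minutes on
one CPU core — and evaluates the seeded 20% held-out split.  These sizes
are the package's own defaults for its built-in verification experiment;
the full published recipe (4 stages from width 64, 200 epochs, 512×512
slices) is expressible through `DNLNetConfig()` / `TrainConfig()` defaults
but is not exercised by the test-suite.

## Known limitations

- 2D only; no volumetric blocks, no 3D reconstruction.
- The concatenation similarity form and criss-cross/asymmetric non-local
  variants are not implemented.
- The complexity certificate counts the f·g attention product; the
  element counts of the softmax matrices themselves differ by (HW/C̄)²,
  so the HW/C̄ ratio is exact for the product, which dominates.
- BN running statistics make train-mode forward passes order-dependent;
  bit-reproducibility holds for a fixed (config, seed, device).
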