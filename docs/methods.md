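# Methods

## Model

The segmentor is an encoder–decoder network with a cross-scale
self-attention bottleneck.

**Encoder.** Five stages with the residual-18 channel plan
(64, 64, 128, 256, 512; the `tiny` plan is 8, 8, 16, 32, 64). Stage 1 is a
7×7 stride-2 stem; stages 2–5 each halve resolution with a stride-2 3×3
convolution followed by one residual block (two 3×3 convolutions with a
skip). Overall downsampling is ×32, so inputs must be divisible by 32;
`segment` rejects other sizes rather than silently padding. Normalization
throughout the segmentor is group normalization: it is batch-size
independent and identical in train and eval mode, which keeps small-batch
CPU training deterministic and removes running-statistics state. Encoder
weights are seeded-random (He initialization); the `pretrained` flag is
accepted for API compatibility but no external weights are bundled, so it
warns and falls back.

**MsST bottleneck.** Stage-2/3/4 maps are bilinearly downsampled
(half-pixel-center convention) to the stage-5 size, each passed through a
3×3 convolution (stride 1, padding 1) to the top channel count, and summed
into the fused map F_A. Queries come from F_A, keys and values from the
top map F_T, via 1×1 convolutions with channel reduction r = 8 for Q and K
(construction rejects channel counts not divisible by r). Attention is the
plain softmax of QᵀK over the key axis after row-major spatial flattening
— no 1/√d scaling, no positional encoding, no multi-head structure, a
single application. The output is F_T + γ·F_M with a single scalar γ
initialized at 0, making a fresh block exactly the identity on F_T; γ
learns how much global context to blend in. An explicit-loop oracle
(`attention_oracle`) re-computes the attention stack without vectorized
shortcuts and the test suite requires agreement within 1e-5.

**Decoder.** Five levels of 2× upsampling + 3×3 convolution + group norm +
ReLU. The first four levels concatenate the matching encoder stage's
features (U-Net skip connections) before the convolution; at 64-pixel
inputs the ×32 bottleneck is only 2×2, and without skips boundary-accurate
reconstruction is not achievable, so the skips are a structural necessity,
not an optional refinement. Upsampling is bilinear by default; a
`transposed_decoder` switch replaces it with zero-insertion upsampling
(the transposed-convolution formulation) for users who prefer learned
upsampling throughout. The head is a 1×1 convolution with a logistic
output, one probability per pixel.

**Discriminator.** A 70×70 patchGAN over 4-channel (RGB image ⊕ mask)
pairs: 4×4 convolutions with strides 2, 2, 2, 1 and widths 64, 128, 256,
512, then a stride-1 4×4 convolution to one logistic score per patch.
`receptive_field` computes the analytic field with the standard recurrence
(rf ← rf + (k−1)·jump, jump ← jump·stride); the `DiscriminatorSpec`
constructor asserts it equals the configured patch size. The discriminator deliberately has no
normalization layers: feature normalization with spatial statistics would
couple distant patches and break the per-patch locality the architecture
exists to provide (verified in tests by a gradient-footprint probe).

## Losses

All terms are mean-reduced (batch-size invariant) negative
log-likelihoods with probabilities clamped to [1e-7, 1−1e-7], so every
term is finite and non-negative:

* BCE: mean over pixels of −[y log ŷ + (1−y) log(1−ŷ)].
* Soft Dice: 1 − (2Σŷy + ε)/(Σŷ + Σy + ε), ε = 1e-6, per image then
  batch-averaged. A soft prediction has no set union, so the sum-of-areas
  denominator is used.
* Adversarial (segmentor side): mean of −log D(x, ŷ).
* Discriminator: mean of −log(1−D(x, ŷ)) plus, when ground truth exists,
  mean of −log D(x, y). Unlabeled batches have no real pairs; the real
  term is omitted by default, with a config switch to resample labeled
  real pairs for balance.

The joint segmentor loss is the unweighted sum BCE + Dice + adversarial;
optional weights (default 1) are exposed only for ablations. The
semi-supervised total is (joint + discriminator) on labeled data plus the
adversarial term on unlabeled data, and reduces exactly to the supervised
loss when the unlabeled set is empty.

## Training protocol

Each iteration draws one labeled batch and (in semi mode) one unlabeled
batch, strictly alternating the two step types. Within a step the
segmentor updates first with the discriminator frozen, then the
discriminator updates on detached predictions — its loss never propagates
into segmentor parameters, and tests assert the segmentor is bit-for-bit
unchanged by a discriminator update. G and D hold disjoint parameter sets
with one Adam optimizer each (classic L2-coupled weight decay).

Full-scale defaults: learning rate 5e-4, weight decay 1e-4, batch size 4,
100 epochs, constant schedule, 512×512 inputs. Model selection keeps the
best validation-Dice weights (last-epoch selection is a config option);
validation defaults to a held-out 25% of the labeled set when no explicit
split is given. Four-fold cross-validation trains one model per fold and
pools held-out per-image metrics; with 354 labeled ids the historical fold
sizes 90/90/90/84 are reproduced, otherwise folds are near-equal.

**Tiny CPU profile** (`TrainConfig.tiny()`): 64-pixel images, the small
channel plans, 10 epochs of 16 iterations each — with eight training
images one sweep is only two batches, so an epoch is defined as a fixed
iteration count with batches sampled with replacement — G learning rate
0.02 (from-scratch training in ~160 steps needs a far larger rate than
the 100-epoch full-scale setting), D learning rate 1e-4, augmentation
off for determinism. The slower critic matters: masks are mostly
background, so an empty prediction already looks locally "real", and a
fast-learning critic pushes a barely-trained segmentor toward predicting
nothing. At full scale (thousands of steps) the shared rate is standard;
at 160 steps the asymmetry is what lets both loss families converge. This
profile trains to held-out Dice ≈ 0.98 in about 30 s on one CPU core.

## Synthetic data

`generate_sample` renders, from a single integer seed: a dark background;
a centered cornea disk (radius 0.35–0.45 of the image, ±2% center jitter)
with a bluish-green base and radial shading; and bright-green lesions as
unions of disks, clipped to the cornea. Phenotypes (radii stated at the
128-pixel reference size and scaled linearly): point_like, 3–15 dots of
radius 1–2 px; point_flaky, dots plus 1–3 patches of radius 4–10 px;
flaky, 1–2 blobs built from 5–15 overlapping disks on a random walk,
lightly Gaussian-smoothed. The mask is the exact lesion support before
Gaussian pixel noise (σ = 5) and ±10% brightness jitter are applied, so
noiseless renders are pixel-perfect. Point-like samples are unlabeled by
default, mirroring archives where such lesions are too small to annotate;
labeled sets draw from the other two phenotypes. The whole generator is a
pure function of (parameters, master seed); datasets regenerate
byte-identically, and child seeds come from a spawned seed sequence.

What the generator does **not** emulate: specular highlights, eyelids and
lashes, uneven fluorescein pooling, camera vignetting, annotation noise,
or inter-patient appearance variation. Passing the tiny trainability gate
therefore demonstrates that the architecture, losses and protocol are
wired correctly and can fit and generalize over this controlled family —
it is not evidence of clinical-grade accuracy on real slit-lamp imagery.

Augmentation applies, each with probability 0.5: rotation uniform in
[−10°, 10°], horizontal flip, vertical flip, additive Gaussian noise, and
a small affine (scale 0.9–1.1, translation ≤5%); image and mask share the
geometric transform, masks use nearest-neighbor interpolation and stay
binary. The probabilities and affine magnitudes are configurable choices,
deliberately mild. Unlabeled images pass through the same pipeline.

## Metrics

Dice = 2TP/(2TP+FP+FN), sensitivity = TP/(TP+FN), Jaccard =
TP/(TP+FP+FN) from per-image pixel confusion counts (binarization
threshold 0.5, inclusive); the identity Dice = 2J/(1+J) is asserted on
every evaluation. Pearson correlation is computed on the soft
probabilities; images where either input is constant yield NaN, are
excluded from the aggregate, and logged. When prediction and ground truth
are both empty the overlap metrics are defined as 1.0 so all-background
controls do not poison averages. Reports aggregate mean ± population
standard deviation and serialize to CSV (one row per image plus summary
rows) and JSON.

## Numerical core

`msstgan.nn` is a reverse-mode autodiff tape over float64 numpy arrays:
elementwise ops with broadcasting, reductions, batched matmul, softmax
(max-shifted), sigmoid/ReLU, 2-D convolution via im2col with a
scatter-add col2im backward, differentiable bilinear resizing built from
per-axis interpolation matrices, and zero-insertion 2× upsampling. Adam
follows the classic formulation with L2-coupled weight decay. A `no_grad`
context disables graph recording so inference frees each layer's patch
matrices immediately (a 512×512 full-plan forward pass runs in ~3 GB).
All gradients are validated against central finite differences in the
test suite. Checkpoints are flat name→array archives; the architecture
lives in the run config, not the checkpoint.

## Problem sizes used in the checks

The bundled end-to-end checks run the tiny profile on an 8-labeled +
8-unlabeled 64-pixel dataset and evaluate on eight freshly generated,
never-trained-on flaky images; attention oracle comparisons use ≤2×8×4×4
instances; the receptive-field probe uses a 256×256 input. These sizes
exercise every code path the full-scale setting uses — the code never
branches on size.

## Known limitations

* No pretrained encoder weights are bundled; real-data experiments start
  from random initialization unless the user supplies a checkpoint.
* The full-scale 512×512 configuration is functional but CPU-slow
  (~20 s per forward pass); the package targets method study and
  small-scale experimentation, not production GPU training.
* Single-class (lesion vs background) segmentation only.
* The adversarial balance at very short horizons is sensitive to the
  critic's learning rate; the tiny profile documents a working setting
  rather than solving GAN scheduling in general.
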