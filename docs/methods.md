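# Methods

## Problem and model

`caafseg` segments small, roughly spherical lesions (pulmonary nodules)
in 2-D grayscale CT patches. The network is a residual U-Net with an
atrous-spatial-pyramid-pooling (ASPP) bridge whose distinguishing
component is *adaptive attention fusion*: every encoder and decoder
stage refines its feature map with two attention branches — position
attention (PA), which reweights spatial locations by pairwise affinity,
and channel attention (CA), which reweights feature channels by
inter-channel affinity — and combines them per sample as

    X_fused = w1 · PA(X) + w2 · CA(X),      w1, w2 ≥ 0,  w1 + w2 = 1.

The pair (w1, w2) is produced by the *adaptive attention controller*
(AAC): the stem feature map is adaptively average-pooled to an 8×8 grid,
flattened row-wise into a sequence of N = 64 C-dimensional vectors, and
passed through single-head scaled dot-product self-attention
(softmax(QKᵀ/√C)·V with C×C projections). The attended sequence is
averaged over positions and mapped by a two-layer MLP (hidden width
⌊C/2⌋, ReLU) to two logits, normalised by softmax. The controller is
therefore input-conditioned: each sample gets its own convex fusion
weights, and they are returned alongside the probability mask so their
population statistics can be reported.

One controller serves the whole network: it consumes the stem features
and its weight pair is broadcast to every fusion block. This matches the
reporting convention of a single per-sample (w1, w2) pair; per-stage
controllers are a possible variant but would produce per-stage weight
pairs with no single summary.

### Architecture details

* Stem: 3×3 conv + BN + ReLU to `stage_channels[0]` at full resolution.
* Encoder: one residual stage per entry of `stage_channels`
  (default 32, 64, 128, 256); stage 1 at stride 1, later stages
  downsample with a stride-2 first convolution. Each residual block is
  two conv–BN–ReLU layers with an identity or 1×1-projected shortcut,
  ReLU after the addition. Default 64×64 input gives the schedule
  64×64×32 → 32×32×64 → 16×16×128 → 8×8×256.
* Bridge: ASPP with 3×3 atrous branches at dilations 6/12/18, a 1×1
  branch and a global-average-pooled branch, concatenated and fused by a
  1×1 convolution back to the input width. At the default 8×8 bridge
  resolution the larger dilations exceed the grid; the branches then see
  mostly padding, which is logged as a warning and tolerated (they
  degenerate towards extra 1×1-like context, and the configuration is
  kept for fidelity to the stated dilation set).
* Decoder: at each level, concatenate with the encoder skip, reduce by a
  1×1 conv, apply the dual-attention fusion block, then bilinear 2×
  upsampling followed by a 3×3 conv (bilinear-then-conv avoids the
  checkerboard artifacts of transposed convolutions). The deepest level
  fuses the bridge output with the deepest encoder features before the
  first upsample; the full-resolution level fuses with the stem-stage
  skip.
* Head: an optional lightweight full-resolution ASPP (same dilations,
  branch width `stage_channels[0]/4`, fused back to the stage width) —
  switchable via `final_aspp` because the pipeline describes a final
  multi-scale refinement distinct from the bridge — then a 1×1
  convolution to one channel and a sigmoid, so outputs are probabilities
  in [0, 1].
* Inputs are min–max normalised to [0, 1] per patch (`normalize_inputs`).

### Position-attention cost

The spatial affinity matrix is quadratic in the pixel count; at 64×64
that is 4096² entries per sample, which is not affordable on CPU. Keys
and values are therefore adaptively average-pooled to at most
`attn_max_positions` positions (default 256, a 16×16 grid) while queries
stay at full resolution, so output shapes and, at sizes at or below the
threshold, exact translation equivariance are unchanged. This trades
fine-grained key resolution for tractability; it is the package's design
choice for desk-scale training.

### Residual scale initialisation

Both attention branches are residual with a learnable scalar scale
initialised at zero, so every fusion block is the identity at
initialisation — small-data training starts from a plain residual U-Net
and learns how much attention to add. A consequence is that at exactly
zero the branch-internal projections (and, because the two branches then
coincide, the controller) receive zero gradient on the first step; the
scales themselves receive gradient immediately, so training unlocks the
branches. The gradient-reachability test raises the scales before the
census for this reason.

## Losses

All losses accept a probability mask P (prediction) and a strictly
binary mask G (target), shaped B×1×H×W.

* **Dice**: 1 − (2ΣPG + ε)/(ΣP + ΣG + ε) per sample, averaged over the
  batch, ε = 1e-6. The matching ε in numerator and denominator keeps the
  perfect-overlap value exactly 0 and defines the empty/empty case as 0.
* **Sobel boundary**: mean |‖∇P‖ − ‖∇G‖| with gradient magnitudes from
  the 3×3 Sobel stencils Sx = [[-1,0,1],[-2,0,2],[-1,0,1]], Sy = Sxᵀ.
  The magnitude is computed as sqrt(gx² + gy² + 1e-12); the tiny
  constant keeps the square root differentiable where both gradients
  vanish and is far below any asserted tolerance.
* **Laplacian boundary**: mean |∇²P − ∇²G| with the 5-point stencil
  [[0,1,0],[1,−4,1],[0,1,0]].
* **EDT-Hausdorff**: d(P→G) + d(G→P) with d(P→G) the mean, over
  foreground pixels of P, of the Euclidean distance transform of G (and
  symmetrically). For a soft prediction the P→G direction relaxes to
  Σ P·D_G / Σ P, differentiable in P; D_P is recomputed from the
  prediction thresholded at 0.5 each step and applied to G's foreground
  as a constant. On binary inputs both directions equal the literal mean
  form, which the brute-force pairwise-distance oracle tests rely on.
  If exactly one mask is empty the mean of the other mask's distance map
  over the full image is charged to both directions (bounded and
  monotone in error); two empty masks give 0.
* **Composite**: Dice + `boundary_weight` × boundary term; the reference
  configuration is the unweighted sum (`boundary_weight = 1`).

Reductions use the mean over pixels so magnitudes are
resolution-independent (the sum form is the mean times N). The 3×3
convolutions use edge-excluding reflect padding (numpy `reflect`, scipy
`mirror`), so border responses are not inflated by an artificial zero
frame; worked-example values that involve border pixels depend on this
choice and the tests pin it against an independent scipy convolution
with the same mode. The ASPP's atrous convolutions use zero padding
instead because large dilations can exceed the reflectable border.

The non-differentiable edge-pair Hausdorff oracle extracts edges as
foreground pixels with nonzero Sobel magnitude of the mask, with the
morphological inner boundary added back so isolated or one-pixel-thin
structures (whose centred stencil response cancels) keep their edge
pixels; a single-pixel mask's edge set is then the pixel itself, making
the oracle comparable with the EDT loss on such masks.

## Metrics

Dice = 2TP/(2TP+FN+FP), IoU = TP/(TP+FN+FP), sensitivity = TP/(TP+FN),
Miss Rate = FN/(TP+FN), specificity = TN/(TN+FP), from per-image
confusion counts at threshold 0.5. Degenerate denominators are defined:
empty target → sensitivity 1 and Miss Rate 0 (nothing to miss); both
masks empty → Dice = IoU = 1 (vacuous success); no true-negative pixels
possible → specificity 1. Per-case metrics are aggregated as mean ± SD
across cases, not pooled over pixels. The ablation statistic is a
two-tailed paired t-test on per-case Dice, t = mean(d)/(sd(d)/√n) with
n−1 degrees of freedom; differences that are constant up to float
rounding are flagged as zero-variance with p = 1 (zero mean) or p = 0.

## Training

AdamW (β = 0.9/0.999, decoupled weight decay 1e-2) at initial learning
rate 1e-4 with step decay ×0.1 every 30 epochs is the reference
protocol; batch size defaults to 8. All of these are exposed in
`TrainConfig`. Training logs per-epoch mean loss and learning rate,
evaluates validation Dice every `eval_every` epochs, keeps the
best-validation-Dice parameters, and aborts with a diagnostic naming the
diverging component if the Dice or boundary term becomes non-finite.
Everything derives from explicit integer seeds: the same (config, seed,
data) triple reproduces every number bit for bit.

The numerical substrate is a minimal numpy reverse-mode autodiff engine
(`caafseg.nn`): float32 tensors, im2col convolution, fused batch
normalisation (batch statistics in training, running statistics at
evaluation, momentum 0.1, biased variance in both places for
consistency), adaptive average pooling with floor/ceil bin edges (so an
average-preserving 2× upsampling pools back to the identical grid), and
half-pixel-centre bilinear interpolation. Scalar operands adopt the
tensor's dtype, which keeps float32 graphs float32; float64 inputs stay
float64, which the finite-difference gradient tests use.

## Synthetic data

The generator renders the five challenge morphologies: C1 smooth
isolated blob (clear boundary), C2 sub-5-px dot among curvilinear
vessel-like distractors, C3 blob adherent to a matched-intensity tube,
C4 bright rim with a depressed cavity (the mask is the rim and has
exactly one hole), C5 star-shaped lesion with radiating spikes. Default
diameters follow representative lesion sizes of 14.83/4.74/19.79/16.45/
25.31 px for C1/C2/C3/C4/C5 at a 1 px ≈ 1 mm scale, jittered ±15% per
fixture; C2 is clamped below 5 px and its discrete footprint trimmed to
stay under the π·(5/2)² area bound. Images are a low-frequency textured
background (≈0.12–0.24) plus the slightly blurred lesion support at
contrast 0.5, distractors where the morphology calls for them, and
additive Gaussian noise σ = 0.05, clipped to [0, 1] — a mild,
realistic noise level for soft-tissue CT patches, chosen once. The mask
is the exact noiseless support of the lesion, excluding distractors.
Per-fixture seeds are spawned from the master seed by counter.

What the generator does *not* emulate: Hounsfield calibration and CT
windowing, reconstruction kernels and streak artifacts, anatomy
(airways, fissures, pleura geometry), partial-volume effects, and 3-D
continuity. Passing tests therefore demonstrate that the architecture,
losses, metrics and harness are implemented correctly and can learn
nodule-like shapes at desk scale — not clinical-grade performance on
real CT.

## Problem sizes used by the tests and the acceptance script

Chosen as the package's own desk-scale demonstration sizes:

* capacity smoke test: default 64×64 model, 8 C1 fixtures, 200 AdamW
  steps at a constant lr 1e-4 (batch 4, i.e. two steps per epoch for 100
  epochs; the step decay belongs to the long protocol and is disabled
  for this short run), training Dice > 0.90;
* convergence-trend and difficulty-ordering checks: a reduced model
  (32×32 inputs, stages 8/16/32) on 32–48 fixtures; the ordering check
  trains at lr 1e-3 for 40 epochs so that learning is far enough along
  for the C1-vs-C2 gap to show;
* acceptance script: the smoke test above, plus a 60-fixture mixed-
  morphology experiment (70/15/15 split, Dice+Hausdorff, lr 1e-3,
  40 epochs) whose test-set metrics and mean fusion weights are
  reported, plus a 40-fixture adaptive-vs-fixed ablation (15 epochs per
  arm) with its paired t-test. At these scales the ablation quantifies
  the harness, not the full-scale effect size; its sign is not asserted
  anywhere.

## Known limitations

* CPU-only, float32; no data augmentation; 2-D only.
* The position-attention key/value pooling above 256 positions is an
  approximation to full spatial affinity.
* Reduced-scale training runs use a higher learning rate (1e-3) than
  the reference protocol so that results are meaningful within seconds
  to minutes; the protocol defaults remain 1e-4 with step decay.
* Checkpoints store parameters in a `.npz` archive with a YAML config
  sidecar validated by hash; they are runtime artifacts, not package
  data.
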