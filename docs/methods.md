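# Methods

## The segmentation problem

Fundus photographs record the retina through the pupil as an RGB image with a
circular field of view (FOV). Retinal vessel morphology is a diagnostic signal
for diabetic retinopathy, and vessel segmentation is the per-pixel binary
labelling of vessel versus background. The package implements a U-Net-family
architecture for this task — the neighbored-attention U-Net (NAU-Net) — along
with its two closest baselines, the attention U-Net and U-Net++, a training
and evaluation pipeline, and a static complexity profiler.

## Network architectures

All three variants share a five-level encoder of double-convolution blocks
(3×3, stride 1, padding 1, each convolution followed by batch normalization
and ReLU) with 2×2/stride-2 max pooling between levels, and the channel
schedule [64, 128, 256, 512, 1024]. Up-convolutions are ×2 nearest-neighbour
upsampling followed by a 3×3 convolution, batch normalization and ReLU.
Outputs pass through a sigmoid, so predictions are probability maps the same
size as the input; inputs must have spatial dimensions divisible by 2⁴.

**Attention U-Net (baseline).** Each decoder level up-convolves the deeper
feature, gates the same-level encoder skip with an additive attention gate
(1×1 convolutions; intermediate width = half the skip width), concatenates
the gated skip with the decoder feature and applies a double-convolution
block. Head: 1×1 convolution. Total parameters: 34,878,573 (34.88 M).

**U-Net++ (baseline).** Nested dense skip pathways: node X(i,j) convolves the
concatenation of all previous nodes at level i with the upsampled X(i+1,j−1);
upsampling carries no parameters, and no deep supervision is used. Head: 1×1
convolution. Total parameters: 36,629,633 (36.63 M).

**NAU-Net.** At each decoder level with width c:

1. *Neighbour fusion.* The deeper encoder map (2c channels, half resolution)
   is up-convolved to c channels and concatenated in front of the same-level
   encoder map, giving a fused skip e′ with 2c channels. At the deepest
   level the decoder's first up-convolution already transforms the bottleneck
   map, which is simultaneously the deepest encoder map; that output is
   reused as the transformed deep map, so there are three dedicated fusion
   up-convolutions for four gated levels.
2. *Attention gating.* An additive attention gate with 3×3 convolutions maps
   the decoder feature d (c channels) and e′ (2c channels) to an
   intermediate width of c/8, forms q = ReLU(W_g d + W_x e′), and produces a
   single-channel attention map α = sigmoid(BN(ψ(q))) ∈ (0, 1) that
   re-weights the fused skip: s = α ⊙ e′.
3. *Merge.* A single 3×3 convolution (+BN+ReLU) maps [d, s] (3c channels)
   back to c channels.

Head: 3×3 convolution to one channel. Total parameters: 37,251,157 (37.25 M).

The three quantities the architectures are pinned against are their published
sizes — 34.88, 36.63 and 37.25 million parameters. The attention U-Net and
U-Net++ constructions coincide with the widely used reference
implementations and reproduce their sizes exactly. For NAU-Net several
wiring details are genuinely open (the gate intermediate width, the number
of dedicated fusion up-convolutions, and how the gated skip enters the
decoder); we resolved them by exhaustively enumerating closed-form parameter
counts over the candidate space and keeping the wiring that reproduces
37.25 M exactly, which is also architecturally coherent (encoder information
flows into the decoder through the gated fused skip, exactly as in the
attention U-Net, with the single merge convolution replacing the double
block). Under the profiler's counting convention this wiring yields 423.5 G
FLOPs at 3×576×576 — between the two baselines, as published, though ~6%
below the printed 449.53 G; since the original profiling tool's conventions
for non-convolution layers are not documented, the parameter audit (which is
exact) was given precedence over the FLOPs figure.

Weight initialization is He-normal for convolutions (BN scale 1, shift 0),
drawn from a generator seeded by `ModelConfig.seed`, so builds are
bit-reproducible. The block ordering Conv→BN→ReLU is the default; the
alternative Conv→ReLU→BN ordering (identical parameter count, different
activation statistics) is available as `block_order="conv_relu_bn"`.

## Loss

Training minimizes the BCE-Dice loss
L = BCE(p, g) + mean_i [1 − (2 S_i + s) / (Σp_i + Σg_i + s)],
where BCE is the per-pixel binary cross-entropy averaged over pixels and
images, S_i = Σ p·g is the soft true-positive count of image i, and s = 1 is
the usual additive smoothing (which makes the term exactly zero for perfect
predictions even on empty masks). The Dice term uses the soft
(probabilistic) counts so it stays differentiable; hard counts are used only
for evaluation. Predictions at exactly 0 or 1 are clamped to ε = 10⁻⁷.

## Metrics and evaluation protocol

Dice = 2TP/(FP+FN+2TP), IoU = TP/(FP+FN+TP), accuracy = (TP+TN)/all,
precision = TP/(TP+FP), computed from per-image confusion counts after
binarizing predictions at threshold 0.5 (pixel-pooled variants are not the
default because the published tables report mean ± standard deviation across
test images, which implies per-image computation). Degenerate cases: Dice
and IoU are 1.0 when both masks are empty; precision is reported as missing
when the prediction has no positives and is excluded from summaries. Both
conventions are logged. Metrics are computed over all pixels of the resized
image; no FOV masking is applied by default. Improvement percentages between
models are 100·(a−b)/b on the metric means.

## Training recipe

Adam with cosine-annealed learning rate: period T_max = 10 epochs, floor
1e-4, 140 epochs, batch size 4; images resized to 576×576 (bilinear; masks
nearest-neighbour, the only mask-safe choice) and channel-normalized with
mean [0.485, 0.456, 0.406], std [0.229, 0.224, 0.225]. The base learning
rate is not part of the published recipe; the Adam convention 1e-3 is the
default and configurable. No validation split or early stopping is used by
default, and augmentation (flips/right-angle rotations) is off by default.
The scheduler follows the closed-form cosine, stepped once per epoch.

## Numerical core

The layers, reverse-mode autodiff, Adam and the scheduler are implemented on
NumPy in `naunet.nn` (float32 throughout). Convolutions are stride-1 and
evaluated as k² batched GEMMs, one per kernel offset; gradients were
validated against finite differences and forward values against SciPy's
cross-correlation. Training is deterministic given the seed on a fixed
machine (a single BLAS configuration), which is what the reproducibility
tests assert.

## Complexity profiler

Parameters are counted by enumerating parameter arrays (equal to the
closed-form sum k²·c_in·c_out + c_out per convolution and 2c per batch
normalization, asserted in tests). FLOPs/MAdds/memory are computed from a
forward-pass trace: the model runs once at 16×16, each operation records its
static descriptors, and costs are re-priced at the requested size by scaling
spatial dims — exact for these fully convolutional networks, and immune to
divergence between profiler and forward pass. Cost rules (n = output
elements): convolution n·(k²c_in + 1 with bias) FLOPs and n·(2k²c_in − 1) +
bias-adds MAdds; BN n/2n; ReLU/sigmoid/add/multiply n/n; 2×2 max pool
4n/3n; upsampling free; memory = 4 bytes × (every operation output + input +
parameters) at batch 1. Under these rules the attention U-Net and U-Net++
come out at 337.1 G and 698.8 G FLOPs at 3×576×576, within 0.1% of their
published values; memory estimates are best-effort and reported without a
hard tolerance.

## Synthetic fundus generator

`generate_synthetic_fundus` emulates the structure the loaders and trainer
need: a circular FOV on a dark border; inside it a radially shaded, smoothly
textured reddish background (Gaussian-filtered noise texture plus i.i.d.
noise, default sd 8); and `n_trees` recursive branching curves radiating
from an optic-disc-like point, drawn as jittered random curves of stamped
disks whose width decays by `width_decay` per generation, rendered dark
(default intensity 60 against background 185 — a high-contrast, low-noise
task). The mask is exactly the set of rendered vessel pixels inside the FOV;
with the default geometry the vessel fraction of the FOV falls in
[0.03, 0.20] across seeds. Everything derives from one seeded generator, so
samples are bitwise reproducible.

What the synthetic task does *not* emulate: real fundus pathology (lesions,
exudates), capillary-scale vessels below the stamping width, inter-annotator
ambiguity, camera vignetting and JPEG artefacts. Passing the held-out-Dice
test therefore demonstrates that the architecture, loss, optimizer and
evaluation machinery work end to end — not that the published benchmark
performance on DRIVE/HRF/CHASE_DB1 is reproduced, which would require the
external datasets and GPU-scale training.

## Problem sizes used in tests

The end-to-end learnability check trains the tiny schedule [8, 16, 32, 64,
128] on 64 synthetic 128×128 images for 30 epochs (batch 4) and requires
held-out Dice > 0.85 on 16 unseen images; reproducibility checks use 2-epoch
runs at 32×32. Full-width models are built and profiled statically but never
trained in the test suite.

## Known limitations

- Only stride-1 convolutions and ×2 pooling/upsampling are implemented —
  sufficient for these architectures, not a general framework.
- U-Net++ upsampling uses nearest-neighbour rather than bilinear
  interpolation (parameter and cost accounting identical; activation values
  differ slightly from implementations that use bilinear).
- The NAU-Net FLOPs figure depends on reconstruction choices discussed
  above; the parameter count does not.
- Checkpoints store weights as float32 `.npz`; no optimizer state is saved.
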