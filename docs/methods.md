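# Methods

This note documents the models, numerical conventions, and design choices
behind `hadet`: an attention-modified single-stage detector for brain-tumor
MRI slices, together with the apparatus needed to exercise it end to end on
one CPU — a synthetic scene generator, an exact profiler, and a miniature
training/evaluation pipeline.

## The detector

The baseline is the public YOLOv11 layout at the *n* scale (width multiplier
0.25, depth multiplier 0.50, channel cap 1024): a backbone of CBS blocks
(conv + batch norm + SiLU) and C3K2 stages ending in SPPF and the C2PSA
multi-head-attention block; an FPN-style neck fusing strides 8/16/32 by
nearest upsampling and concatenation; and three decoupled heads, each with a
CBS box branch that predicts four side offsets as discrete distributions
over 16 bins, and a depthwise-separable class branch. At a 640×640 input
the heads cover 80² + 40² + 20² = 8,400 candidate positions. The heads'
intermediate widths are shared across scales and derived from the stride-8
head's incoming width (64 channels at the *n* scale) — this detail is load-
bearing for the parameter accounting below.

The modified variant makes three substitutions:

1. **Dual-channel attention replaces C2PSA.** Two parallel convolutions
   (3×3 and 5×5) over the 256-channel post-SPPF map, concatenated, fused by
   a 1×1 convolution back to the input width, followed by a spatial-attention
   map computed from the fused tensor; the block's output is the *input*
   multiplied by that sigmoid map, so the block is multiplicative in its
   input (zero input ⇒ zero output; all-zero weights ⇒ output = x/2).
2. **Shuffle3D replaces the first convolution of each head branch** (the
   first CBS of the box branch, the first depthwise convolution of the class
   branch). Shuffle3D is parameter-free, so the following convolution's
   input is widened to the head's incoming channel count; no projection is
   added. This widening, not an extra layer, is what reproduces the
   published parameter decrease.
3. **Spatial attention gates the raw network input.** A 7×7 convolution
   (stride 1, padding 3) over the stacked channel-max and channel-mean
   descriptors, squashed by a sigmoid and multiplied with the input. It
   costs 99 parameters anywhere; placed on the 640×640 input it costs
   ≈0.08 GFLOPs, which is the only insertion point consistent with the
   published ablation (+Spatial leaves parameters unchanged at 2.59 M while
   raising GFLOPs from 6.4 to 6.5). The full variant's published statistics
   (2.52 M / 5.9 GFLOPs) correspond to all three substitutions together,
   which is why `build_ha` includes the input gate.

### Shuffle3D

Channel rearrangement followed by a spatial-inhibition energy gate. The
rearrangement defaults to the deterministic group interleave with 4 groups
(the reshape–transpose permutation of grouped convolutions: with C channels
and g groups, channel `c` moves to position `(c mod C/g)·g + ⌊c/(C/g)⌋`);
an alternative `random` mode draws a seeded uniform permutation once per
block so downstream convolutions train against a stable order. The gate is
computed independently per (batch, channel) slice of an H×W map:

    e = Σᵢⱼ xᵢⱼ / (H·W − 1)
    u = (x − e)² / (4·(e + α)) + β
    y = sigmoid(u) · x

with regulators α = 10⁻⁴ and β = 0.5. The formula is implemented exactly
as written, with the slice statistic `e` (a mean-like term with an N−1
denominator) in the normalizing denominator. The parameter-free attention
family this gate descends from normally places the slice *variance* there;
because the as-written form is most likely intended, it is the default, and
an opt-in `variance=True` switch computes Σ(x−e)²/(H·W−1) instead. The gate
needs H·W ≥ 2 and multiplies every element by a value in (0, 1), so
|y| < |x| wherever x ≠ 0.

### The HKCIoU loss

Box regression uses CIoU,

    CIoU = IoU − ρ²(b_p, b_t)/c² − α·v,
    v = (4/π²)·(arctan(w_t/h_t) − arctan(w_p/h_p))²,
    α = v / (1 − IoU + v),

reweighted through the hook function f(x) = a·x + b/x, which is strictly
convex on x > 0 with its minimum at √(b/a) — exactly 1 for the default
a = b = 0.5. The hook multiplies the CIoU *loss* L = 1 − CIoU:

    HKCIoU(L) = f(L)·L = a·L² + b.

The product form is evaluated through this algebraic identity, which is
finite at L = 0 (value b) and removes the division. Its gradient 2aL is
larger than the plain CIoU-loss gradient for poor boxes (L > 1) and smaller
for good ones (L < 1) — amplified penalties where localization is bad,
damped churn where it is already good. The reweighting is written on the
loss rather than on the raw CIoU value because only that reading produces
the intended amplification; a `metric` mode applying a·CIoU² + b is kept
for comparison. The constant offset b makes absolute HKCIoU values
incomparable to plain CIoU loss; comparisons across the two configurations
should use mAP, not loss magnitudes.

The total training loss is the standard three-term sum
L = α·L_box + β·L_obj + γ·L_cls with L_box = L_CIoU + L_DFL. The weights
are not part of the published recipe; the defaults follow this detector
family's common practice: 7.5 on the IoU term, 1.5 on the distribution
focal term, 0.5 on classification. The architecture is anchor-free with no
separate objectness head, so the confidence role is played by the per-class
binary cross-entropy over all 8,400 candidates; `w_obj` is retained as a
configuration alias and reported as zero in loss breakdowns. The
distribution focal loss supervises each box side's bin distribution through
the two bins adjacent to the continuous target t: with l = ⌊t⌋,
DFL = −[(l+1−t)·log p_l + (t−l)·log p_{l+1}]; reg_max = 16 bins; a target
landing exactly on the top bin is supervised through the last bin pair.

## Profiling conventions

Parameters count every learned tensor: convolution kernels, biases where a
convolution has one (attention-block convolutions and final head
convolutions; CBS convolutions are bias-free), batch-norm scale/shift
pairs, plus the 16 frozen weights of the integral decoding projection.
FLOPs are 2 × the operation count of convolution kernels, convolution
biases, and batch-norm scale/shift (2 ops per normalized element), at a
given input size — the accounting used by the profilers this model family
is conventionally reported with. Activations, pooling, nearest upsampling,
concatenation, and the attention matmuls inside C2PSA are not counted.
Under these conventions the baseline at 4 classes profiles to 2,590,620
parameters (2.59 M) and 6.38 GFLOPs (prints 6.4) at 640×640; the full
variant to 2,520,418 (2.52 M) and 5.86 (prints 5.9); the Shuffle3D-only
variant to 2.47 M; the Dual-channel-only variant to 2.64 M.

The Dual-channel block's internal widths are not published; they are pinned
by the Dual-channel-only variant's published 2.64 M total. Branch widths of
channels_in/2 would add over a megaparameter and are impossible under that
constraint; branch widths of channels_in/8 (32 channels at the 256-channel
site; with 3×3/5×5 branches, the 1×1 fuse, and the 7×7 spatial-attention
gate the block holds 9218·32 + 355 = 295,331 parameters) land the variant
on 2.64 M exactly, so channels_in//8 is the default. The closed-form per-node
arithmetic and the instantiated network's tensor count are asserted equal in
the test suite, so the profiler cannot drift from the runtime model.

## Synthetic scenes

The generator emulates the schema of the public four-class brain-MRI
detection dataset (glioma / meningioma / no tumor / pituitary; 4,737
training and 512 validation images with fixed per-class counts, YOLO-format
labels). Scenes are axial-slice caricatures: dark background, bright skull
ring, speckled brain ellipse (mean 90, σ 8 on a 0–255 scale), and for tumor
classes one elliptical lesion with class-conditional priors — gliomas
mid-bright (195–210) with a lobular outline, meningiomas darker (145–160),
round and displaced toward the cortex, pituitary lesions small, central and
very bright (232–248). Lesion axes are drawn as fractions of the image
side (gliomas 9–16 %, meningiomas 8–14 %, pituitary 4.5–8.5 %). The
intensity ranges are disjoint, so a mean-intensity threshold classifies
annotated regions with high accuracy — the generated task is learnable by
construction, which is what makes miniature training runs meaningful.

"No tumor" images carry one annotation covering the brain region, mirroring
the emulated dataset's labeling, where the detector reports "no tumor" as a
detectable class with its own PR curve.

Bounding boxes are recomputed from the rendered lesion mask (min/max of
foreground pixels), not from the generating ellipse, so emitted labels are
tight by construction. Labels are written at six decimal places and round-
trip losslessly. One master seed drives everything; per-image seeds are
derived with a splitmix64 mix, so generation is reproducible and order-
independent. Default image size is 640 (8-bit PNG, grayscale replicated to
three channels); miniature runs use 96.

What the generator does **not** emulate: MRI physics and acquisition
artifacts, anatomical detail, multi-lesion images, ambiguous class
boundaries, or annotation noise. Passing micro-training checks therefore
demonstrates that the losses, assignment, optimization, and evaluation
chain works — not that the detector reaches any particular accuracy on real
MRI data.

## Training and evaluation at miniature scale

The numerical stack is a small reverse-mode autodiff engine on numpy
(convolution via an im2col/BLAS path with grouped and depthwise fast paths,
max pooling, nearest upsampling, softmax, batch norm with running
statistics), written for this package because the environment provides no
tensor-autodiff library; gradients of every primitive are verified against
central differences in the test suite.

The optimizer is SGD with the published recipe (initial learning rate 0.01,
momentum 0.937, weight decay 5·10⁻⁴, decay applied to kernels only),
with a 3-epoch linear warmup and constant rate thereafter (the published
schedule beyond the optimizer settings is not specified). Micro runs use
100 training images at 96×96 (the anchor grid is then 12² + 6² + 3² = 189),
batch size 8, 20 epochs — sized so that a full run takes about two minutes
on one CPU while still moving the loss by an order of magnitude.
Augmentation is horizontal flip plus multiplicative brightness jitter;
mosaic-style augmentation and its end-of-training schedule are out of scope.

Target assignment is a deliberately simple, enumerable rule rather than the
task-aligned assigner of the reference implementation (which is not
described in the source material): an anchor point is positive iff it lies
inside a ground-truth box and the box's longer side falls in its stride's
pixel range (≤64 px → stride 8, 64–128 → stride 16, >128 → stride 32),
with ties going to the smallest box. The rule is checked against an
exhaustive brute-force oracle.

Inference decodes each candidate's side distributions by softmax
expectation, filters by class confidence (default 0.25) and applies greedy
per-class NMS at IoU 0.7. Evaluation is COCO-style: greedy confidence-
ordered matching (one match per ground-truth box), 101-point interpolated
precision, mAP50 at IoU 0.5 and mAP50–95 averaged over IoU 0.50:0.05:0.95;
classes absent from the ground truth are skipped, not scored zero. The
evaluator is cross-checked to 10⁻⁶ against an independent implementation
(shapely-based geometry, explicit per-point interpolation) in the tests.

Full-scale claims — mAP50 ≈ 96.8 % and mAP50–95 ≈ 79.5 % on the real
Kaggle dataset, FPS, and cross-model comparisons — require the external
data and GPU-scale training and are explicitly out of scope; the package's
checks are the structural statistics, the loss/attention/evaluator
properties, and miniature learnability (held-out synthetic mAP50 > 0.5
averaged over seeds for both the CIoU and HKCIoU configurations).

## Numerical details and edge cases

- Energy gate: H·W = 1 slices are rejected (the N−1 denominator); non-
  finite inputs are rejected rather than propagated.
- CIoU: α is defined as 0 when IoU = 1 and v = 0 (coincident boxes); the
  batched differentiable form adds 10⁻⁹ regularizers to every division and
  propagates gradients through α (no stop-gradient), so analytic and
  numeric gradients agree to 10⁻⁴.
- Degenerate boxes (w ≤ 0 or h ≤ 0) are rejected at construction.
- Channel shuffle requires the group count to divide the channel count;
  group mode is bit-deterministic, random mode is seeded.
- Batch norm uses ε = 10⁻³ and momentum 0.03 on running statistics
  (biased variance for normalization, unbiased for the running estimate).
- Convolution weight init is He-normal driven by an explicit generator;
  every build is bit-reproducible from its seed.
- NMS breaks score ties by index order; the brute-force reference in the
  tests uses the same tie-break.

## Known limitations

- The C2PSA interior follows the public reference layout; the source
  material does not redefine it, and only its parameter/FLOP totals are
  anchored by published numbers.
- The published GFLOP figures for two single-substitution ablation rows
  (+Shuffle3D 5.8, +Dual-channel 6.5) are mutually inconsistent with the
  other rows under any fixed convention; this package reproduces the
  baseline and full-variant figures exactly and reports computed values
  (5.7, 6.4) for those two rows.
- Training at full 640×640 resolution works but is impractically slow on
  one CPU (per-step cost scales with image area, ~44× the miniature
  setting); the miniature protocol exists precisely to keep the full chain
  exercisable.
- The random-permutation mode of Shuffle3D fixes its permutation at module
  construction; re-permuting every forward pass is representable but not
  the default, since a stable order is what downstream convolutions train
  against.
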