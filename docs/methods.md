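# Methods

## Problem and model

The task is three-class semantic segmentation of low-altitude aerial imagery
of a row crop: background soil (0), crop plants (1), weeds (2). The two
vegetation classes form a hierarchy — every crop pixel is a vegetation
pixel — and the model is built around that structure rather than treating
the three classes symmetrically.

A U-Net-style encoder–decoder predicts two sigmoid probability maps,
vegetation `P_veg` and crop `P_crop`, from one forward pass. The crop map is
softly confined to predicted vegetation,

    P̂_crop = P_crop · P_veg^γ,    γ = 0.75,

and the weed map is *derived*, not predicted:

    P_weed = max(P_veg − P̂_crop, 0).

Consequences that the test suite verifies as invariants: `P_weed ≤ P_veg`
everywhere; wherever `P_veg ≥ P̂_crop`, the decomposition is conservative
(`P̂_crop + P_weed = P_veg` to machine precision); both outputs are
monotone in their inputs. The γ-scaling is applied identically at training
and inference — applying it only during training would break conservation
at test time. Operating in probability space preserves boundary
uncertainty; a hard XOR of binarized vegetation/crop masks flips uncertain
boundary pixels to weed, and the suite contains a constructed example where
the two routes disagree.

Masks are assembled by thresholding with crop precedence (crop if
`P̂_crop ≥ t_crop`, else weed if `P_weed ≥ t_weed`, else background).
Defaults are `t_crop = t_weed = 0.3`; `t_weed` is independently
configurable because the subtraction lowers weed probability magnitudes,
and a validation sweep (`metrics.threshold_sweep`, grid 0.10–0.50 step
0.05, objective = mean of crop and weed Dice) typically selects a lower
weed threshold when weed probabilities are attenuated.

## Decoder details

- **Spatial attention** on skips: single-channel sigmoid gate from a 1×1
  convolution, multiplied into the skip features. Gate weights start at
  small variance with zero bias, so gating begins near 0.5 and the output
  magnitude never exceeds the input.
- **Vegetation Global Context** bottleneck: `V` comes from a dedicated
  sigmoid 1×1 convolution on the last encoder stage — distinct from the
  final vegetation head and without its own loss (gradients arrive through
  the block). Masked global pooling uses `ε = 1e-6` in the denominator;
  with `V ≡ 1` it reduces to global average pooling. The excitation uses a
  reduction ratio of 4.
- **UpBlocks**: bilinear ×2 upsampling with half-pixel-center sampling (no
  corner alignment — the dominant convention in modern segmentation
  stacks), gated skip, channel concatenation, then two 3×3 convolutions
  each followed by ReLU. No normalization layers anywhere in the decoder.
- **Heads**: the stride-4 decoder output is the finest level; the dual
  1×1 heads and the three auxiliary 2-channel heads emit logits at their
  stage resolutions, bilinearly interpolated to the input extent before the
  sigmoid/loss. Auxiliary heads are dropped at inference.

### Reference widths and size accounting

The decoder's channel widths are not uniquely determined by the published
description; they were calibrated against the published size budget of the
ConvNeXt V2 Tiny configuration (32.52 M parameters). With bottleneck 320
and UpBlock widths (144, 80, 48) the model lands at 32.55 M parameters
(0.09 % above budget) and 18.06 G MACs per 480×352 forward pass (0.7 %
above the published 17.93 G). `count_params` excludes the auxiliary heads
by default (they are inference-discarded and contribute ≈ 5×10⁻⁴ M, below
the printed precision); `count_macs` counts each convolution/linear
multiply-accumulate once, during a real forward pass, and ignores
interpolation and elementwise work, matching standard per-layer counters.

## Losses

With `G_veg, G_crop, G_weed` the binary targets (satisfying
`G_crop + G_weed = G_veg`):

    L_veg  = Dice(P_veg, G_veg)   + λ_bV·Bound(P_veg, G_veg)
    L_crop = BCE(P̂_crop, G_crop) + Dice(P̂_crop, G_crop)
             + λ_bC·Bound(P̂_crop, G_crop)
             + 0.5·Dice(P̂_crop·G_veg, G_crop·G_veg)
    L_weed = 0.7·Dice(P_weed, G_weed) + λ_bW·Bound(P_weed, G_weed)
    L_total = λ_V L_veg + λ_C L_crop + λ_W L_weed + Σ_{k=1..3} λ_aux L_aux_k

Defaults: λ_bV = 0.3, λ_bC = 0.05, λ_bW = 0.3, λ_aux = 0.05, λ_V = 1.3,
λ_C = 1.6, λ_W = 1. Each `L_aux_k` is the unweighted mean of the Dice
losses of the k-th auxiliary head's vegetation and crop channels (no
γ-scaling at auxiliary heads). The crop BCE consumes the γ-scaled `P̂_crop`.

Numerical choices:

- **Dice smoothing**: `s = 1` added to numerator and denominator, making
  empty-vs-empty a well-defined zero loss. The raw overlap form (`s = 0`)
  is available and used by the hand-computed oracle tests on nonempty
  inputs.
- **Boundary Dice**: edge maps are `clip(ReLU(x ∗ K), 0, 1)` with the 3×3
  Laplacian stencil `K = [[1,1,1],[1,−8,1],[1,1,1]]` and zero padding (the
  spurious border frame affects prediction and target symmetrically). The
  clamp matters: raw rectified responses reach 8, and soft Dice is only a
  set similarity — loss guaranteed in [0, 1] — for inputs in the unit
  range; binary-mask contours are unaffected (they become exact binary
  edge masks).
- **BCE clamp**: probabilities confined to `[1e-7, 1−1e-7]` before logs.
- **γ-power floor**: `P_veg` is floored at `1e-6` inside the constraint so
  the `γ < 1` power stays differentiable at zero.

## Training protocol

AdamW (lr 1e-4, weight decay 1e-4 by default), cosine-annealed learning
rate over the full run (period = total epochs, minimum 0, no restarts),
50 epochs, batch size 4, ImageNet standardization
(mean (0.485, 0.456, 0.406), std (0.229, 0.224, 0.225)), random 80/10/10
whole-patch split, no data augmentation. After every epoch the validation
score — the mean of crop and weed Dice at the configured thresholds — is
computed and the best-scoring weights are kept. Two stability options sit
on top: global gradient-norm clipping (default 1.0) and optional linear
learning-rate warmup (default off). Warmup matters for short high-lr runs:
without it, aggressive early Adam steps can drive the head sigmoids to
saturation, freezing the loss with vanished gradients. Seeding covers
initialization and data order; CPU runs are bit-deterministic.

## Implementation substrate

The package runs on a compact reverse-mode autodiff engine over NumPy
(`weedseg.autodiff`): tape-built backward closures, im2col convolution,
depthwise convolution, matrix-product bilinear resampling, layer
normalization, and broadcast-aware elementwise ops, with numerical-gradient
tests for every primitive. The same convolution/linear primitives report
multiply-accumulate counts to a context-managed counter, so MAC accounting
is exact by construction. ConvNeXt V2 Tiny is implemented shape-faithfully
(4×4 stride-4 stem + LayerNorm; four stages of depths 3/3/9/3 at dims
96/192/384/768; blocks of depthwise 7×7 → LN → 1×1 expand ×4 → GELU →
global response normalization → 1×1 project, residual) and randomly
initialized — parameter and MAC counts depend on shapes only. FastViT,
RepViT and MambaVision remain registry entries with declared channel
signatures; they require pretrained weights the package does not bundle and
raise a clear error on instantiation.

## Synthetic fields

The generator (`weedseg.synthetic`) emulates the structure that matters for
this task, with exact masks by construction:

- soil: a palette brown modulated by smooth Gaussian-filtered illumination
  (σ = 18 px, ±25 %) plus fine speckle;
- crops: "rosettes" — unions of 5–9 overlapping rotated ellipses — on a
  jittered planting grid, mimicking transplanted row crops with compact,
  regular canopies;
- weeds: thin random-walk filaments (default 1–3 px wide) and small
  blotches scattered over bare soil, never overlapping crops;
- color: crop green at hue 100°, weeds offset by +15° (configurable), so
  the classes are separable but not trivially; saturation/value jitter
  stays inside the HSV green-filter band, which is what lets the repair
  tool recover the vegetation support of a generated image with IoU ≥ 0.95
  (measured 1.0 at default palette).

Not emulated: perspective, shadows, occlusion, growth stages, leaf texture,
illumination color casts. Passing tests on these fields therefore
demonstrate mechanism correctness (the architecture can learn and represent
both classes; the hierarchy, losses and metrics behave as specified), not
field-ready accuracy on real drone imagery.

## Dataset repair

Public versions of this kind of dataset can contain misnamed patch↔mask
pairs. The repair procedure extracts a binary vegetation mask from each
patch with an HSV green filter (defaults: hue 60–170°, saturation ≥ 0.15,
value ≥ 0.15 — a broad band tolerant of shade and bloom; the thresholds are
configurable) and compares it against the vegetation support of every
candidate ground-truth mask, assigning the nearest (1-NN). The distance is
the Hamming count of disagreeing pixels (1 − IoU selectable); ties break
lexicographically by mask id and are reported as ambiguous. Ground-truth
masks are never modified. On shuffled synthetic sets the exact inverse
permutation is recovered.

## Evaluation

Per-class IoU and Dice, mIoU over all three classes (background included),
overall pixel accuracy, and Cohen's kappa, computed from a 3×3 confusion
matrix summed over all test patches before any ratio is taken
(micro-averaging; the alternative — averaging per-image scores — is not
used, and reports are labeled accordingly). Classes absent from both
reference and prediction score IoU = Dice = 1 by convention, which is
irrelevant under micro-averaging. Throughput (images/s) is measured over
the full fetch-to-threshold loop and reported informationally.

## Problem sizes used by the test suite

CPU-scale settings keep the full suite near one minute: the fixture
encoder (channels 8/16/32/64, ~25 k parameters) with a narrow decoder;
synthetic patches of 32–96 px; the overfitting check uses 8 patches at
96×96 with 4–6 px weeds (so weed structures span more than one stride-4
cell), lr 1e-2 with 20 warmup steps, and 200 full-batch iterations. The
reference ConvNeXt V2 Tiny model is instantiated once for size accounting
only and is never trained here — reproducing the published accuracy scores
requires GPU-scale training on the original drone dataset and is outside
the scope of this package's tests.

## Known limitations

- No pretrained encoder weights; real-data accuracy claims cannot be
  validated in-package.
- The NumPy substrate is single-threaded-friendly but orders of magnitude
  slower than a GPU framework; it targets correctness and testability, not
  throughput.
- The decoder widths are a calibrated reconstruction (see "Reference
  widths"); other width assignments can match the same parameter budget.
- Whether the published size budget includes the auxiliary heads is
  undecidable at the printed precision; they are excluded by default.
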