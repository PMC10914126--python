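# Methods

## The tiling scheme

An image is reflection-padded on the bottom/right so both dimensions are
multiples of the feature-map ratio `F`, partitioned into a row-major grid
of non-overlapping Zones of Responsibility (ZoRs) whose edge is the
stride, and each ZoR is expanded by the halo on every side, clipped at the
image bounds (outside the image there is no true context to add, and the
whole-image pass sees the same zero padding there). Each expanded tile is
run through the network, the prediction is cropped back to the ZoR, and
the crops are stitched into the output canvas, which is finally cropped to
the original image size. Coordinates are 0-based half-open rectangles;
tile traversal order is row-major (irrelevant to the output, fixed for
reproducible logs). The last row/column simply hold shorter tiles — every
size in play is a multiple of `F`, so the network accepts them directly.

All ZoR origins, halos and tile edges being multiples of `F` is what makes
per-tile feature maps subgrids of the whole-image feature maps: a stride
that is not a multiple of `F` builds the downsampled maps from differently
aligned pixel blocks and changes the output (demonstrated by
`stride_offset_experiment`, which finds RMSE = 0 exactly at offsets
≡ 0 mod F).

## Halo arithmetic: three related quantities

1. **`compute_halo`** — the classical per-convolution sum
   `Σ 2^{l_c}·⌊k_c/2⌋` over the longest path. Up-convolutions and 1×1
   convolutions contribute zero; only under that convention does the sum
   reproduce the established values for both U-Net (92, with 2×2
   up-convs) and FC-DenseNet-56 (377, with 3×3 transposed convs). Skip
   connections are assumed not to lengthen the receptive field beyond the
   deepest path (skip branches are prefixes of it); joins are validated to
   occur at equal level.

2. **`receptive_margins` / `exact_halo`** — the exact requirement. The
   per-conv sum describes the receptive-field reach of an output pixel
   sitting on an aligned pooling phase; other phases inherit the reach of
   their widest pooled sibling, and a 3×3 stride-2 transposed convolution
   makes odd-phase outputs depend on one extra coarse cell on the
   trailing side. `receptive_margins` computes the true worst-case
   leading/trailing reach beyond an F-aligned block edge by walking the
   layer sequence backward with integer interval arithmetic for each of
   the F phases; `exact_halo` rounds the maximum up to a multiple of F
   and is the tiler's default planning halo. For U-Net at depth 5 the
   margins are (94, 94), so the conventional F-rounded halo of 96 is
   already exact — the published arithmetic survives. At depth 3 the
   margins are (22, 22) against a per-conv sum of 20 (itself a multiple
   of F = 4, so rounding adds nothing), and the toy DenseNet's trailing
   margin exceeds its per-conv sum by one cell per up-conv; in both cases
   tiling at the per-conv halo demonstrably leaves seams and tiling at
   `exact_halo` is bitwise exact. The brute-force perturbation probe
   (below) agrees with the walk on every architecture tested.

3. **`support_radius_oracle`** — the measured value. For every input
   pixel of a probe image, a unit perturbation is applied and the change
   of the central F×F aligned output block is recorded (one forward pass
   per pixel); the result is the worst reach of an influencing pixel
   beyond the block's edges. The probe raises an inconclusive error if
   the support touches the probe border, rather than returning a lower
   bound.

## The deterministic engine

The forward engine exists so that "tiled equals whole-image" can be
asserted bitwise rather than within a tolerance. Convolutions accumulate
`bias + Σ over (dy, dx, c_in)` in a fixed loop order using only
element-wise numpy arithmetic — no BLAS or FFT reductions, whose internal
blocking can depend on operand shape and would reorder floating-point
sums between a 512² tile and a 1024² image. All arithmetic is float64.
SAME convolutions zero-pad by `⌊k/2⌋` (reflection padding is applied only
to the whole image to meet the size constraint, never inside layers — the
halo guarantees zero-pad corruption at tile edges never reaches a ZoR).
The transposed convolution is the adjoint of a stride-2 SAME convolution;
max-pooling is 2×2 stride 2; batch normalization uses frozen per-channel
statistics (identity by default for seeded untrained models, in which
case it is exactly a no-op); the activation is ReLU and the output head a
per-pixel softmax over 2 classes by default (4-class models are one
argument away). Ties in the argmax break toward the lowest class index.
There is no batch dimension: one tile at a time, matching the out-of-core
memory contract (peak working set = one tile + the output canvas).

**Linear probing mode.** Receptive-field probes run the engine with
identity activations, *average* pooling in place of max pooling, and no
softmax. This makes the map exactly affine, so an impulse response
isolates a pixel's influence exactly and no perturbation can be hidden by
a dead ReLU or an unselected max; outside the receptive field the
difference of the two passes is bitwise zero. Average pooling has the
same spatial footprint as max pooling, so the measured support is that of
the real network.

**Seeded weights.** `seeded_weights` draws kernels from
`Generator(PCG64(seed))` in a fixed order — zero-mean Gaussians with
variance `2/fan_in` (He scaling, keeping activations alive through deep
ReLU stacks), zero biases, identity batch-norm. Same seed, same bits, any
platform.

## Error metrics

Comparing a reference single-pass softmax output `R` with the tiled
output `T` over `K` images of `m×n` pixels: RMSE is
`(1/K)·Σ_k sqrt(Σ(R−T)²/(mn))` over all channels; ME is the mean count of
argmax disagreements per image (reported with the sample standard
deviation across the K images, 0.0 for K = 1); MER is ME/(mn). ME = 0 is
the operative criterion: the segmentations are identical with and without
tiling.

## Synthetic study conditions

The verification experiments use standard-normal noise images (mean 0,
sd 1) and seeded untrained networks. Tiling exactness is a property of
the spatial arithmetic, not of the weights or the image content, so this
is the hardest honest test: random weights have full effective receptive
fields (nothing has learned to ignore context), and noise images have no
smooth regions that could mask seams. What these fixtures do *not*
exercise is model accuracy on real tissue — no claim about segmentation
quality follows from them, only about the tiling transport being exact.
The blob generator (soft-edged elliptical foreground on noise, with
ground-truth masks) exists for visually meaningful demos, not for the
exactness proofs.

Problem sizes are chosen for desk-scale runtimes: the headline
tiled-vs-whole comparison runs a depth-5 U-Net at 1024² with 512-pixel
tiles (halo 96, ZoR 320); the halo sweep runs 0…96 in steps of 16 at
640² with K = 2 images; stride offsets 0…32 use 256² windows; brute-force
receptive-field probes use toy architectures (halo ≤ ~25) where one
forward pass per input pixel is affordable. Channel widths of the
untrained models are reduced (2–4 base channels instead of the published
64) because exactness and seam errors depend on spatial arithmetic, not
width; everything is configurable back up to the published scale.

## Numerical and design choices

* Halos passed to the planner must already be multiples of F; raw values
  are rejected rather than silently rounded, so a deliberately undersized
  halo in an error experiment is always explicit.
* The halo-sweep reference is a single whole-image forward pass on the
  padded image, cropped back; the reference and every tiled run see
  identical padding.
* The stride-offset experiment compares outputs over the region common to
  all windows, inset by the exact halo and re-aligned per offset, so
  window-border effects cannot contaminate the comparison; RMSE at an
  aligned offset is then exactly 0.0, not merely small.
* The effective-receptive-field estimate has no backward pass to lean on:
  sensitivity is measured by central finite differences (step 1e−3) of
  the pre-softmax logits on standard-normal inputs, or exactly by impulse
  superposition in linear mode. The support threshold (fraction 1e−4 of
  the peak sensitivity, configurable) is a genuine free parameter — there
  is no canonical value — and the resulting reach is rounded up to a
  multiple of F. The estimate cannot exceed `exact_halo`: kernels can
  ignore information but not grow.
* Weight archives are `.npz` files with a manifest (architecture name,
  seed); loading validates every shape against the architecture.
* Whole images are held in memory; the tiler bounds *model* memory (one
  tile per forward pass), not image memory. A chunked-array backend would
  slot in at `run_tiled_inference`'s canvas without changing the scheme.

## Known limitations

* The engine is a verification instrument, not a production inference
  runtime: pure numpy, single-threaded, float64. Bit-exactness claims are
  about this engine; frameworks with nondeterministic reduction orders
  will show float-epsilon seams even with a correct halo.
* Dilated convolutions, attention, deformable and other dynamic
  receptive-field layers are out of scope; the declarative config schema
  rejects them.
* `valid_output_size` requires even sizes at every pooling stage and
  reports an error otherwise rather than guessing a floor convention.
* SegNet and FCN-VGG16 are not provided as builders: their published halo
  values depend on path assumptions (e.g. a value that is not a multiple
  of the natural F) that cannot be pinned down reliably, and guessing
  would defeat the point of exact arithmetic.
* The transposed-convolution margin analysis follows the engine's adjoint
  convention (leading offset `(k−1)//2`); a framework with a different
  transposed-conv padding convention shifts which edge carries the extra
  cell but not its size.
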