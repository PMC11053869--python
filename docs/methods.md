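# Methods

## The DHConv layer

A DHConv layer with `M` input channels, `N` filters, kernel size `K`
(odd), dilation rate `r` and large-kernel fraction `P` assigns, within each
filter, `M·P` channels a dilated `K×K` kernel and the remaining `M·(1−P)`
channels a pointwise `1×1` kernel. Validity requires `1/P` and `M·P` to be
integers. The layer is computed as two summed branches:

* the **dilated branch** convolves with the large kernels on the dilation
  grid, padded by `r·(K−1)/2` per side;
* the **pointwise branch** is a `1×1` convolution on the remaining
  channels, unpadded.

Both branches are spatially aligned under this same-padding convention, so
a stride-1 layer maps an `H×W` input to an `H×W` output and is a drop-in
replacement for a standard `K×K` convolution. One bias per filter is shared
across both branches — a filter is one unit regardless of its kernel mix.
Stride subsamples the full stride-1 output identically on both branches.

**Channel layout.** Which channels of a filter carry the large kernel is a
free choice. The default `shifted` layout marks channel `c` of filter `f`
large iff `(c + f) mod (1/P) = 0`, so every input channel is covered by a
large kernel in the same fraction `P` of filters (when `N` is a multiple of
`1/P`); a `leading` layout (first `M·P` channels of every filter) is also
provided. The staggered default follows the heterogeneous-convolution
lineage the layer descends from and avoids starving any input channel of
spatial context; the pictorial sources for this design do not pin the
arrangement down, so it is exposed as a parameter.

**Initialization.** All taps are drawn from a normal with standard
deviation `sqrt(2 / fan_in)`, where a filter's fan-in counts each kernel's
true footprint (`K²` vs 1 per channel). Seeded everywhere.

**Degeneracies.** `P = 1` makes the layer an ordinary dilated convolution;
additionally `r = 1` makes it an ordinary standard convolution. These are
exercised as test identities against an independent scipy-based dense
convolution.

**Verification oracle.** `dense_oracle` materializes every
(filter, channel) kernel as a dense `K_D×K_D` array with `K_D = (K−1)·r+1`
— large kernels scattered onto the dilation grid, pointwise kernels as a
single centre tap — and performs one ordinary dense convolution. It also
counts the structural multiply–accumulates (support positions × output
pixels). The branch evaluation and the oracle agree to 1e-5 over an
exhaustive grid `K ∈ {1,3,5}, P ∈ {1/4,1/2,1}, r ∈ {1,2,3}, C,N ∈ {4,8}`,
and the oracle's MAC count equals the analytic cost formula on the same
grid. Receptive field is measured by impulse probing (which input pixels
elicit a nonzero central response in an all-ones-weight probe layer) and
equals `(K−1)·r + 1` for all tested `K, r`.

## Cost model

FLOPs are counted as multiply–accumulates (no ×2 for the accumulate),
biases excluded, and — by default — convolutions only; normalization,
activation, pooling and fully connected heads are excluded (dense heads can
be included on request). This matches the convention in which the analytic
ratio `R = P + (1−P)/K²` is derived; that ratio concerns the converted
convolutions themselves, which is why a whole backbone converts by less
than the per-layer factor. Ratios are exact `fractions.Fraction` values;
tests compare them at 1e-12 or exactly.

A layer whose `C·P` is not a whole number is rejected. `N·P` need *not* be
whole: the large kernels are allocated per filter across its channels, and
the pointwise cost term `D_w·D_h·C·(N − N·P)` is integral whenever `C·P`
is.

## Backbone conversion

`resnet50_conv_layers` describes the 53 convolutions of a ResNet-50 (stem,
16 bottleneck blocks of 1×1/3×3/1×1, four downsample projections) with
propagated spatial dimensions. The default conversion policy replaces
every 3×3 convolution inside the bottleneck blocks — exactly 16 layers —
with a DHConv of `P = 1/4, r = 2`, preserving channels and stride; the stem
and all 1×1 convolutions are never touched. The policy text this follows
("replace three of the four 3×3 kernels per filter group") is read as
per-filter channel replacement within each 3×3 layer, not as dropping
layers; dilation is applied uniformly across stages. Conversion of an
actual weighted layer copies the dense weights verbatim when
`P = 1, r = 1` (numerical identity) and, for `P < 1`, keeps the original
`K×K` weights on surviving positions while pointwise entries inherit the
original kernel's centre tap.

## The compact detector

The environment targeted by this package is CPU-only, so the detector is a
deliberately compact fully convolutional network rather than a full
two-stage Mask R-CNN (no feature pyramid, region proposals, or RoIAlign):

* 3 → 8 standard 3×3, ReLU
* 8 → 16 DHConv (policy's `P, r`), ReLU
* 16 → 16 DHConv, ReLU
* 16 → 1 pointwise head, sigmoid foreground probability.

Instances are the 4-connected components of the thresholded probability
map (mask binarization threshold 0.5, minimum area 16 px), scored by mean
foreground probability, with tight boxes derived from the masks. Forward
and backward passes are hand-written numpy (gradients verified against
finite differences); training is SGD with momentum 0.9, weight decay
5e-4, and a step schedule `lr(e) = lr₀ · 0.1^⌊e/10⌋` with default
`lr₀ = 0.001` over up to 50 epochs. The training target is the union of the
instance masks (foreground vs background, binary cross-entropy). The head
bias is initialized to −2 so an untrained network predicts background
everywhere instead of speckle — the standard background-prior
initialization for rare-foreground problems.

This keeps the package's claims honest: what is demonstrated end to end is
that the DHConv backbone trains stably and that training improves panoptic
quality on held-out synthetic scenes — not that this compact network
matches a full Mask R-CNN. Smoke training uses 8 images of 128×128, 3
epochs, `lr₀ = 0.05` (a conventional setting for a small pixelwise-BCE
network trained for ~50 SGD steps), and finishes in seconds on one CPU.

## Metrics

Matching is one-to-one at an IoU threshold, default 0.5 — the panoptic
convention, under which the match set is unique; below 0.5 predictions
claim truths greedily in descending confidence. Precision = TP/(TP+FP),
Recall = TP/(TP+FN), count-based Dice = 2TP/(2TP+FN+FP); any zero
denominator yields 0 so degenerate scenes evaluate rather than error. TN
is recorded in the match table but enters no formula.

AP is the area under the all-point-interpolated precision–recall curve
obtained by sweeping the *confidence* threshold at fixed IoU: an integral
over recall is only realizable by ranking predictions, so the
"threshold-sweeping" reading is implemented as score sweeping, with an
optional COCO-style mode averaging AP over IoU ∈ {0.50:0.05:0.95}.
PQ = DQ·SQ with DQ = TP/(TP+FN/2+FP/2) and SQ the mean matched IoU.

Because count-based Dice is bounded by detection performance while
reported segmentation Dice values in the literature often reflect pixel
overlap, a pixel-level Dice (mean `2|A∩B|/(|A|+|B|)` over matched pairs)
is exposed as a clearly separate quantity; neither is privileged.

## Annotation I/O

COCO 2014 dialect: five top-level sections, polygons as flat coordinate
lists, 0-based pixel units, `(x, y, w, h)` half-open boxes. Rasterization
samples pixel centres `(j+0.5, i+0.5)` with even-odd (XOR) combination
across rings, so interior rings cut holes. Mask-to-polygon tracing unions
the pixel squares of each 4-connected component (via shapely) and emits
its boundary rings with integer-corner vertices; with centre sampling this
makes `polygon_to_mask ∘ mask_to_polygon` exact, which the round-trip
tests assert bit-for-bit. Crowd annotations with uncompressed RLE are
decoded to masks on read; written output always uses polygons. Degenerate
zero-area polygons rasterize to an empty mask with a warning rather than
an error.

## Synthetic scenes

Each cell is an ellipse whose boundary radius is modulated as
`ρ(θ) = 1 + a·Σ w_k cos(kθ+φ_k)` (k = 2, 3; amplitude `a < 1`), rasterized
on pixel centres — cheap, controllable, and star-convex. Placement
enforces a pairwise overlap cap (fraction of the smaller mask) with
rejection sampling; an impossible packing raises after 1000 attempts.
Rendering paints cells in z-order at a jittered foreground intensity over
the background, Gaussian-blurs, adds Gaussian noise, and clips to 8-bit;
full per-instance masks are kept as ground truth even where occluded.
Images are grayscale, replicated to 3 channels for the detector stem.

Preset parameters encode the qualitative regime contrasts of the public
cell benchmarks they emulate (deformed/large vs many/low-contrast vs
high scale variance vs adherent/overlapping); the specific radii,
intensities and noise levels are this package's choices of plausible
values, fixed once and documented in `synthgen.PRESETS`. What passing
tests show is that the pipeline is correct and trainable under controlled
conditions; synthetic ellipse scenes do not capture textured cytoplasm,
uneven illumination, debris, or annotation noise, so no claim about
absolute accuracy on real microscopy data follows from them.

## Numerical choices and limitations

* Exact rational arithmetic for all cost ratios; float comparisons at
  1e-5 (single-precision-style layer equivalence) or 1e-12 (identities).
* Convolution via strided window views + einsum; padding is zero-fill.
* Matching ties (equal scores) resolve by input order; deterministic.
* Determinism everywhere via `numpy.random.default_rng(seed)`; training is
  deterministic given its seed up to floating-point accumulation order.
* The detector cannot separate touching cells of the same connected
  foreground component (no instance head); overlapping-cell presets are
  therefore exercised through metrics and I/O, not through detector
  accuracy claims.
* `TrainableDHConv` supports stride 1 only; strided inference is available
  in the functional layer but is not trained.
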