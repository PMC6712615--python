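# Methods

## The problem setting

A whole-slide pathology image carries one diagnostic label, but a CNN is
trained on fixed-size patches cropped from it.  Propagating the slide label
to every patch mislabels exactly those patches of a non-normal slide that
contain (almost) no lesion tissue.  The package's premise is that a
classifier's own confidence can be used to find and remove such patches from
the training pool before a stronger classifier is trained.

## Patch extraction and augmentation groups

Patches are cropped on a regular grid with stride `s = round(w·(1−overlap))`;
windows that would cross the right/bottom edge are discarded rather than
padded, so a W×H slide yields `(⌊(W−w)/s⌋+1)·(⌊(H−w)/s⌋+1)` patches.
Coordinates are 0-based `(x, y) = (column, row)` with half-open windows
`[x, x+w)`.  For sparse slides an Otsu threshold on luminance (tissue =
darker side, 3×3 majority smoothing) gives a region-of-interest mask; a
window is kept when at least 50% of its pixels are foreground.  Near-constant
images are resolved by brightness alone (dark ⇒ all tissue, bright ⇒ all
background); the 50% in-RoI criterion is a symmetric default.

Each kept patch is expanded into an *augmentation group*: the four rotations
followed by the vertical flip of each rotation (the 8 poses of the dihedral
group of the square, original included, `aug_index` 0–7), or rotations only
(4 poses).  All transforms are exact array re-indexings; a group shares its
slide, grid position and propagated label.

## The cleaning loop

One iteration of the reverse-active-learning loop:

1. the confidence model predicts class probabilities for every training
   patch (each orientation variant scored by its own forward pass);
2. a patch is flagged when its maximum probability is **strictly** below the
   confidence threshold θ (default 0.5);
3. group consensus: when strictly more than half of a group's members are
   flagged (more than 4 of 8, generalized to "more than half" for groups of
   4), the entire group is removed; otherwise only the flagged members are;
4. the model is fine-tuned — the same weights continue training on the
   reduced pool (warm start, one short epoch at learning rate 0.01) — and
5. accuracy is measured on a fixed validation set with trustworthy labels.

The loop stops when validation accuracy has not improved for
`stop_patience` iterations (default 1), when an optional absolute accuracy
target is reached, when an iteration removes nothing, or at
`max_iterations` (default 4).  The final reduced pool is returned.  Two
guards cover cases the removal rules leave open: an iteration that would
empty the pool aborts with a diagnostic (an uninformative model flags
everything), and an optional per-iteration removal cap (off by default) can
bound the removal rate.

For two-class problems the maximum of a softmax is ≥ 0.5 by construction,
so the default threshold never flags anything; the threshold is configurable
and a warning is issued when K = 2.

## Architectures

**RefineNet** is deliberately small so it stays near-calibrated rather than
memorizing the pool: six 3×3 convolutions (16, 32, 64, 64, 128, 128 maps)
each followed by 2×2 max pooling except the last, which feeds an average
pool that consumes the whole remaining map, then FC-256 and the K-way head.
The input side must be a multiple of 32 (224 gives the reference 7×7 average
pool; 64 gives 2×2); anything else is rejected with the computed shape trace.

**ADN** is a wide, shallow DenseNet variant.  Each ADC dense layer is an
atrous 3×3 convolution whose dilation alternates 2, 3 across layers,
followed by a common 3×3 convolution that fuses the multiscale features;
both emit k maps and the fused output joins the running concatenation, so
dense layer *l* receives k₀ + k·(l−1) channels.  Three modules with growth
rates 8, 16, 32 (four dense layers each) sit between a 16-map stem
convolution + max pool and a head of two 1×1 convolutions (128, 64 maps),
global average pooling and the FC classifier.  The weighted-layer budget of
this reference configuration is 1 + 3·4·2 + 2 + 1 = 28.  Because that
budget is itself a structural invariant, the transitions between modules are
parameter-free 2×2 average pools rather than pooling plus a compression
convolution — adding transition convolutions would break the 28-layer count
that the builders enforce under `strict_reference`.  The head's internal
widths (two 1×1 convolutions) are a design choice made to fit the same
budget.  The alternating-sequential reading of the paired atrous/fusing
convolutions is likewise a decision; a parallel two-branch wiring would be a
different, also-defensible reading.

Dilated kernels span `kernel + (kernel−1)(γ−1)` pixels at constant parameter
count, which the graph code exposes (`effective_kernel_extent`,
`parameter_count`) and the tests assert.

## Training backend and numerics

No deep-learning framework is used: the package compiles its layer graphs
into a compact numpy CNN engine — stride-1 'same' convolutions via im2col
and BLAS matrix multiplication, 2×2 max pooling, non-overlapping average
pooling, batch normalization (eps 1e-5, running-stat momentum 0.9), PReLU
(initial slope 0.25), He-normal initialization, float32 throughout.
Optimization is mini-batch SGD with momentum 0.9, batch size 16, under the
staged schedule 0.05 → 0.01 → ×0.1 per further stage; the large first rate
is workable because every weighted layer except the head is followed by
batch normalization.  Batches of fewer than two samples are skipped (batch
norm needs a batch).  An optional per-epoch step cap subsamples each pass
without changing the schedule semantics.  For a fixed seed, initialization
and batch order are fixed; bitwise identity across BLAS builds is *not*
promised — the reproducibility contract is statistical, except for the pure
selection stages (flagging and consensus are exact functions of the
predicted probabilities).

Patches are mapped to float32 in [−0.5, 0.5]; when a model's configured
input side differs from the stored patch size, integer-factor resizing uses
block averaging and anything else falls back to bilinear resampling.

## The synthetic generator

Each class is a band-limited texture: white Gaussian noise smoothed with a
Gaussian kernel of σ = 1/(2πf) for a class-specific spatial frequency f
(0.02–0.33 cycles/pixel), normalized to unit variance and added, at
contrast 0.16 with fixed per-channel weights, to a class RGB palette.
Classes therefore differ in both color and granularity — learnable by a
small CNN in minutes, yet overlapping enough that confidence is informative.

Non-normal slides start as class-0 (normal) texture and accrete random
ellipses of the label's texture until the tumor mask covers the target area
fraction (within half a percentage point; each new ellipse's area is capped
by the remaining deficit so the target is never overshot).  Lesions are
multifocal: a single blob is capped at 4% of the slide area.  That
lesion-size scale is what makes the reference conditions (tumor fraction
0.3, 64×64 patches at 50% overlap on 256×256 slides, purity threshold 0.1)
mislabel roughly a fifth of the corpus — the regime this package targets,
in which correctly-labeled tissue still dominates every texture so that
confidence-based removal is selective rather than wholesale.

Ground truth: a patch's true label is the slide label when its tumor-pixel
fraction reaches the purity threshold (default 0.1), else class 0.  The
generator's per-slide seeds derive from the corpus seed by fixed hashing, so
a corpus is byte-reproducible from its config.

## Reference experiment and problem sizes

The bundled end-to-end experiment uses 4 classes, 8 training slides per
class (4 validation slides per class from a disjoint seed), 256×256 slides,
64×64 patches at 50% overlap — 49 per slide, 1,568 base patches, 12,544
after 8-fold augmentation — with RefineNet at its 64×64 input and ADN at a
32×32 input.  Schedules are two stages (0.05, 0.01) of one epoch each with
per-epoch step caps of 150 (RefineNet) and 250 (ADN) batches, up to two
cleaning iterations with patience 1 and 150-step fine-tunes.  These problem
sizes were chosen so a five-seed battery trains well past chance on a single
CPU core; the texture task saturates quickly, and longer schedules mainly
reduce run-to-run variance.

What the experiment shows — and what it cannot.  Mislabeled patches whose
window overlaps a lesion fringe are *detectably* ambiguous, and the loop
removes them with near-perfect precision.  Mislabeled patches that are pure
normal texture are, by construction, statistically identical to the
correctly-labeled normal patches from class-0 slides; no confidence rule can
separate those two sub-populations, so removal recall plateaus well below 1
while precision stays high.  Real tissue is more heterogeneous than the
generator (stain variation, tissue subtypes), which plausibly makes real
mislabeled patches easier to single out; passing here therefore validates
the selection mechanics and the directional benefit of cleaning, not
clinical-grade performance.

## Known limitations

* No stain simulation, scanner artifacts, or pyramidal WSI formats; slides
  are flat RGB images.
* The generator's normal texture is identical inside and outside cancer
  slides (see above) — a deliberately hard regime for confidence-based
  cleaning.
* The two-class threshold semantics are inherently degenerate at θ = 0.5.
* Slide-level vote fusion breaks ties by mean probability, then lowest class
  index — a deterministic convention, not the only possible one.
* Multi-class F-measure is reported both macro- and micro-averaged, since
  either averaging is defensible.
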