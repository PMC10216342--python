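# Methods

## Problem and labels

Whole-slide images of H&E-stained colorectal tissue are segmented
pixel-wise into five classes — tumor (0), stroma (1), necrosis (2), mucus
(3), background (4) — with a sixth *artifact* label (5) marking regions
excluded from training and evaluation. Predictions never contain the
artifact class. The tumor–stroma ratio of an ROI is
TSR = 100·tumor/(tumor+stroma) percent; necrosis, mucus and background
pixels contribute to neither numerator nor denominator, so the score stays
defined in necrotic or mucinous regions. Note the field's naming
inversion: a *high* TSR (much tumor) is called *stroma-low*. Ties at a
category cutoff are assigned to stroma-low so categorization is a total,
deterministic function; consequently the 50 % and 65 % cutoffs disagree
exactly on TSR ∈ [50, 65).

## Encoder

Both models share a MobileNetV2-style feature extractor truncated after
its 16th inverted-residual bottleneck, with that bottleneck's final 1×1
projection convolution removed. In the standard 17-bottleneck layout the
14th bottleneck halves resolution a fifth time; to keep the contracted
output stride at exactly 16 (a 32×32 feature mask for a 512×512 input) the
stride of that stage is set to 1 here. The feature dimensionality at the
cut is whatever the expansion arithmetic yields — 6·⌈160α⌉₈ channels at
width multiplier α (960 at α = 1.0, 720 at α = 0.75) — reported by the
builder, not hard-coded. Initialization is random by default; a checkpoint
load path exists for externally pre-trained weights but nothing in the
test suite requires one.

Patches are standardized per patch and per channel to zero mean and unit
SD before the encoder; the SD divisor is floored at 1e-8 so constant
channels map to zero. Per-patch normalization is the only variant that
needs no dataset statistics.

A `SmallEncoder` (three to four conv–BN–ReLU6 blocks, configurable
strides) exposes the same interface for desk-scale experiments.

## Basic Prototype Network

Annotations are downsampled to the feature grid as *fractional coverage
weights*: weight(c, cell) = fraction of the native pixels in the cell
labeled c (area averaging rather than nearest-neighbor, which would erase
thin structures). Per support s and class c, masked average pooling gives
v(s, c) = Σ w·f / Σ w over cells; the prototype is the unweighted mean of
v(s, c) over the supports containing c. Similarity is −½‖x − p‖². Query
score maps are computed per cell, bilinearly upsampled (half-pixel-aligned
sample centers) to native resolution, then argmaxed; ties break to the
lowest class index. Upsampling scores before the argmax is deliberate —
bilinear interpolation of categorical labels is ill-defined.

The training loss is pixel-wise over feature cells:

    L = CE + γ·R

where CE is the cross-entropy of the softmax over prototype similarities
against the fractional target weights, and R (prototype attraction) is the
mean over labeled cells of ‖f − p_true‖², the true class being the cell's
majority (argmax-weight) class. γ defaults to 0.5. Cells that are partly
artifact enter CE with proportionally reduced weight; fully-artifact cells
are excluded everywhere, including prototype pooling. The two-term form is
this package's documented reading of a correlation-regularized loss whose
original formulation is not reproduced here; γ = 0 reduces exactly to
cross-entropy.

Episodic training: each episode samples a fixed number of supports per
class and query images (without replacement within the episode, with
replacement across episodes), rebuilds prototypes from the supports,
scores the queries, and applies one Adam step (lr 5e-4 at full scale).
Validation every `validate_every` episodes; the best-scoring weights are
kept. The multi-run evaluation protocol draws `ns` support patches
(interpreted as a total count, with per-class presence enforced by
resampling and logging) `draws` times per model and reports mean ± SD of
the metrics across all runs.

## U-Net baseline

The decoder has four blocks; each upsamples 2× (nearest-neighbor),
concatenates the encoder output of the same spatial size (strides 8, 4, 2
— the final block is at native resolution, where no encoder counterpart
exists, so it has no skip), then applies two 3×3 conv + batch-norm + ReLU
stages. A final convolution with neither batch norm nor activation maps to
one score map per class. Default decoder widths (256, 128, 64, 32) follow
a conventional halving schedule and are configurable. Training uses
pixel-wise cross-entropy with artifact pixels masked out; each batch holds
`images_per_class` patches per class, a patch belonging to the class of
its majority non-artifact pixel area (the least arbitrary assignment
rule). Adam, lr 2e-4, α = 0.75 at full scale to keep parameter counts
comparable to the BPN.

## Tiling

Coordinates are 0-based with half-open rectangles. Method A tiles at
stride = patch size, shifting the last row/column so patches end at the
image edge; overlaps are resolved by row-major overwrite (no averaging).
Method B discards a 96 px boundary per 512 px patch (active area 320×320,
39.06 % of the patch) and tiles at stride 320 so every pixel is written
exactly once; border patches keep their border-side margins. When an image
dimension is not stride-divisible the final patch is shifted to end at the
edge and its active region clipped to the yet-unwritten remainder,
preserving exact-once coverage.

## Evaluation and agreement statistics

The confusion matrix is 5×5 (rows ground truth, columns prediction);
ground-truth artifact pixels are skipped. Per-class recall, precision,
IoU and F1 follow the usual TP/FP/FN formulas; macro averages weight
classes equally, dropping classes absent from both ground truth and
prediction; a class that appears but has zero true positives scores 0
(avoids rewarding vacuous classes).

Continuous rater agreement uses the two-way, absolute-agreement,
single-measure ICC (McGraw–Wong A,1): with mean squares MS_R (rows/
subjects), MS_C (columns/raters), MS_E (residual),

    ICC = (MS_R − MS_E) / (MS_R + (k−1)MS_E + k(MS_C − MS_E)/n)

with the standard F-distribution confidence construction
(Satterthwaite-approximated denominator df). The "mixed vs random"
distinction affects interpretation only, not the point estimate. Perfect
tables (MS_E = MS_C = 0) short-circuit to ICC = 1 with a degenerate CI;
zero between-subject variance is an explicit error. Cohen's kappa uses
marginal-product chance agreement; the 0/0 case (both raters constant)
deterministically returns 1 under perfect agreement, else 0.

Deviation summaries average model-minus-observer TSR differences over
ROIs whose segmentation-quality grade (mean of two graders' 1–10
integers) meets a threshold (default 9.0), isolating ROIs where the mask
is trustworthy so residual deviations reflect observer bias. The A–D
categorization partitions the (deviation, quality) plane with defaults
quality_good = 7.0 and deviation_large = 20 pp, both explicit knobs:
A = poor quality & large deviation, B = good & large, C = good & small,
D = poor & small.

## Synthetic data

Scenes are seeded Voronoi tessellations (cell count ≈ area/region_scale²)
whose lookup coordinates are warped by a smooth random displacement field,
giving organic region boundaries while the label map stays exact. Cells
are assigned to classes greedily in descending area order by largest
remaining target deficit, so realized fractions track requested ones
(within ±5 pp for typical configurations where a cell is ≲1 % of the
image; very coarse configurations are correspondingly looser). Textures
loosely mimic H&E: tumor = dark-purple nuclei blobs (thresholded smoothed
noise) on lavender; stroma = oriented sinusoidal pink fibers with smoothly
varying direction; necrosis = pale unsmoothed speckle; mucus = smooth
light blue-gray; background = near-white. Base colors are jittered per
scene and Gaussian pixel noise added. Not modeled: physical 0.22 µm/px
calibration (metadata only), nuclei instances, stain variation across
slides, signet-ring-cell morphology — a known real-data failure mode.
Passing tests on these scenes therefore demonstrate the correctness of the
pipeline's mechanics and learnability of class-distinct textures, not
clinical-grade performance on real histology.

Dataset generation draws per-image class fractions from a Dirichlet
centered on the template (concentration 8) so scenes vary in composition
and every class occurs as a majority class somewhere. Splits are disjoint
with at least one image each; a per-split class-pixel census is emitted.

Rater simulation: estimate = clip(100·truth + bias + ε, 0, 100) with
ε ~ N(0, σ²), seeded. Additive Gaussian with clipping was chosen over a
Beta model as the simplest mechanism matching an additive-bias analysis.

## Scaled study conditions

The full-scale protocol (512×512 patches, α = 1.0/0.75, 10,000 episodes /
5,000 steps, batch 25) is impractical to rerun routinely on one CPU, so
the test suite and `scripts/acceptance.py` use a fixed desk-scale
protocol: 128×128 scenes over tumor/stroma/background in equal thirds
(16 images, region scale 48 px), a SmallEncoder (output stride 4 for the
BPN; stride 16 with a (16, 12, 8, 8) four-block decoder for the U-Net),
200 BPN episodes with 2 supports per class and 1 query, 300 U-Net steps
with 2 images per class. Equal thirds guarantee each class appears as a
majority patch, which the U-Net batch-composition rule requires. At seed 0
these conditions yield held-out pixel accuracies of ≈0.97 (BPN, from 0.80
untrained) and ≈0.98 (U-Net, from 0.38 untrained).

## Numerical choices

All network arithmetic is float64, so prototype, similarity and loss
values can be compared against brute-force recomputation at 1e-10.
Argmax ties resolve to the lowest class index everywhere. Batch-norm uses
running statistics (momentum 0.1) at evaluation. Adam uses the standard
bias-corrected moments (β₁ = 0.9, β₂ = 0.999, ε = 1e-8). All randomness
flows from a single integer seed per run; identical seeds give
bit-identical weights, histories and generated data.

## Limitations

* The exact decoder filter counts and the original formulation of the
  correlation-regularized loss are not public in the sources available to
  this package; documented defaults stand in for both.
* The synthetic generator's simplifications (above) mean reported
  accuracies say nothing quantitative about real H&E slides.
* The NumPy core is single-threaded aside from BLAS; full-scale training
  is out of its intended scope.
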