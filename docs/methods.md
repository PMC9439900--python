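# Methods

## Scope and model

`texfuse` classifies two-class grayscale radiograph-like images by
fusing handcrafted texture descriptors into a convolutional
classifier. The pipeline is: preprocess (crop → min–max normalize →
bilinear resize) → texture feature images (LBP + HOG, stacked as a
2-channel image) → two-branch network joined by element-wise Add
fusion → stratified k-fold training and evaluation. The assumptions
are those of the underlying approach: the discriminative signal is
local second-order texture (not global shape or intensity), images are
single-channel, and the task is binary.

## Preprocessing

All internal images are float arrays in [0, 1]; 8-bit quantization
happens only at file boundaries. Min–max normalization maps a constant
image to zeros (the degenerate case must be defined somewhere; zeros
propagate harmlessly through every later stage). Cropping defaults to
the largest centered square — radiographs commonly carry lateral
background bands, and a square crop also makes the square resize
aspect-preserving; `fixed_margin` and `none` are available, and with
`none` the resize is allowed to change aspect ratio. Interpolation is
bilinear. Normalization happens before texture extraction; the LBP
codes are invariant to that choice by construction (they depend only
on intensity *orderings*), and HOG feature images are per-image
normalized at render time, so the ordering is not load-bearing.

## LBP

Neighbor enumeration is fixed package-wide: neighbor 0 is east,
enumeration proceeds counter-clockwise, bit *i* carries weight 2^i.
Ties (neighbor equal to center) set the bit, per the ≥ sign convention.
The grid variants (`default`, `ror`, `uniform`, `nri_uniform`, `var`)
use the exact 3×3 neighborhood at R=1, P=8; `circular` samples P
points at radius R with bilinear interpolation and applies no
post-mapping. `var` is the population variance (divide by P) of the P
neighbor intensities; it is the default variant because contrast
information is the strongest texture cue for opacity-like lesions.
Borders are replicate-padded so the code map has the input's extent (a
full-resolution image the network can consume); a `valid` mode keeps
only interior pixels.

Numerical choices: circular sample offsets are rounded to 1e-6 so
cardinal samples land exactly on grid points (cos π/2 is ~6e-17 in
floating point, which would otherwise flip exact ties), and
interpolated samples and centers are rounded to 1e-10 before the ≥
comparison so a mathematically exact tie remains a tie regardless of
summation order. Rendered images divide integer codes by the largest
possible code (255, 9, or 58 depending on variant); the unbounded
`var` map is min–max normalized per image.

## HOG

Gradients are unscaled central differences (interior magnitude of a
unit-step ramp is 2), replicate-padded at borders like the LBP module.
The orientation is the quadrant-aware angle of (F_y, F_x), folded to
[0°, 180°) by default; a `signed_gradients` switch keeps the full
circle. An `orientation_formula: as_printed` option computes the angle
of (F_x, F_y) instead — the transposed form that sometimes appears in
print — which reflects all angles about 45°; the conventional form is
the default and both are tested.

Cells are non-overlapping squares (default 2×2, the finest scale;
choices {2,4,8,16,32} are accepted), with trailing partial cells
dropped. Each pixel votes its magnitude into the two bin centers
nearest its angle with linear interpolation and circular wrap, so
per-cell histogram mass exactly equals per-cell gradient magnitude
(asserted to 1e-9). There is no block normalization: the descriptor is
rendered to an image rather than fed to a linear classifier, and the
per-image min–max normalization at render time plays that role.
Rendering defaults to dominant-bin magnitude per cell, which preserves
cell resolution at cell size 2 where oriented glyphs are unreadable; a
`glyph` mode draws weighted oriented lines.

## Fusion network

The backbone is VGG-16's conv stack (stages of 2,2,3,3,3 convolutions,
widths 64,128,256,512,512, each stage closed by a 2×2 max-pool) with a
reduced head: two hidden fully connected layers (width 4096 scaled by
the width multiplier), dropout 0.5 after each, and a 2-unit output.
The texture branch has independent weights and mirrors the backbone's
stages up to the fusion position; sharing weights across the two
heterogeneous inputs is available as an ablation (`share_weights`) but
requires matching input channel counts. The stacked 2-channel texture
input and a single branch is the default reading of the two-operand
Add; `texture_mode: separate_branches` runs one branch per texture
channel and sums the outputs into the same fusion.

Fusion happens after the last convolution of the chosen block, before
that block's max-pool (the per-block description is taken as
authoritative over the looser "after the pooling layer" phrasing). The
fusion kernels K_i are learnable per-channel 1×1 weights initialized
to 1, so training starts from a plain element-wise sum and the
"dimensionality unchanged" property holds trivially; the standalone
`add_fuse` op additionally supports arbitrary odd kernels
(cross-correlation convention, zero padding) for analysis. At
`fusion_position: input` there is no texture branch: the depth channel
is broadcast to the texture channel count and fused directly, and the
backbone's first convolution takes that channel count.

There is no autodiff framework underneath: forward and backward passes
are hand-written numpy, with 3×3 convolutions evaluated as nine
shifted GEMMs (float32 throughout). Backprop is verified against
central finite differences in the test suite. Weight initialization is
He-uniform, seedable; no pretraining of any kind is used. Input sizes
must be multiples of 32 (five 2× pools).

## Training and evaluation

Defaults mirror the full-scale operating point: Adam, learning rate
1e-4, 50 epochs, batch 64, no early stopping, unweighted 2-class
cross-entropy (inverse-frequency class weights are deliberately not
applied by default; a flag could be added, but the baseline behaviour
is unweighted). For the desk-scale experiments shipped with the
package (64×64 inputs, width multiplier 1/8, 10 epochs) the operating
point is learning rate 3e-4 and batch 16: with a 5× shorter schedule a
modestly larger step size and more updates per epoch are needed for
the optimizer to converge, and 1e-3 was found to destabilize training
of this depth of network without normalization layers.

Folds are stratified and seed-deterministic (per class, sizes differ
by at most one); scikit-learn's StratifiedKFold provides the partition
behind the `FoldPlan` surface. Metrics are computed from per-class
one-vs-rest confusion counts; averaging is support-weighted by default
because in a binary task weighted recall is algebraically identical to
accuracy — the signature visible in this family of results tables —
with macro averaging available. Division-by-zero precision/recall
(a class never predicted) is defined as 0 with a logged warning.
`run_experiment` trains one network per fold with fold-derived seeds,
continues past a failed fold (logging the cause), and writes
metrics.json / predictions.csv / resolved_config.yaml / log.txt.

## Synthetic data

The generator emulates what matters to this pipeline and nothing more:
a smooth background (Gaussian-filtered white noise, correlation length
6 px, plus a vertical brightness gradient), optional low-amplitude
horizontal sinusoidal bands that exercise HOG's orientation response
the way rib shadows would, and — for the positive class only — 2–4
blurred Gaussian blobs (radius 4–9 px, intensity delta 0.25) carrying
speckle noise (σ 0.12) that shifts local variance and gradient
statistics. Lesions are placed inside a central elliptical "lung
field" so class membership cannot leak through border artifacts.
Defaults are 64×64 images so full cross-validation runs in minutes;
224×224 is accepted for full-architecture smoke tests. Images are
quantized to 8 bits in memory so the array path and the PNG round trip
are bit-identical, and generation is bit-deterministic under a fixed
seed.

What the phantom does *not* model: anatomy, acquisition physics,
scanner/site variation, label noise, class imbalance, or lesion
diversity. Passing tests therefore demonstrate that the pipeline is
correctly implemented and can exploit a textural class signal — not
that any accuracy level transfers to clinical radiographs.

The `texture_separation_check` diagnostic summarizes each image by its
LBP code histogram plus mean HOG cell energy, scores the distance
between class-mean feature vectors (features standardized beforehand),
and attaches a label-permutation p-value (999 permutations by default,
+1-corrected). With zero effect sizes its rejection rate is consistent
with the nominal level (checked over seeded replicates), and the score
is non-decreasing in the lesion intensity delta.

## Problem sizes

The shipped experiments use 100 images per class at 64×64, width
multiplier 1/8, 2-fold cross-validation and 10 epochs, repeated over
three seeds for the fused/ablation comparison; these sizes keep a full
run in the minutes range on a single CPU core while leaving the
learning signal far from floor or ceiling. The full-scale
configuration (224×224, width multiplier 1, 5-fold, 50 epochs) is
expressible in the same configs but is a GPU-scale undertaking and is
not exercised by the shipped tests.

## Known limitations

- The network trains on CPU via numpy GEMMs; it is adequate at the
  shipped scales but not a practical engine for 224×224 full-width
  training.
- Per-fold training from scratch with ~100 images is inherently
  high-variance; individual seeds can land anywhere from ~0.83 to 1.0
  accuracy under the shipped conditions, which is why directional
  claims are made by seed majority.
- `nri_uniform` label tables are defined for P=8 only; grid variants
  are fixed at R=1, P=8 (the circular variant generalizes both).
- Only PNG/JPEG ingestion; no DICOM, windowing, or lung segmentation.
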