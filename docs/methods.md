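# Methods

## Detection network

The detector is a u-net: a contracting path of paired 3×3 convolutions whose
filter counts double at each of `depth` levels (default 4) starting from
`base_filters` (default 8), 2×2 max-pooling between levels, a bottleneck at
`base_filters · 2^depth` channels, and an expanding path of 2×2 stride-2
transposed convolutions concatenated with the same-level contracting feature
maps. Every convolution uses "same" zero padding so the output probability
map shares the input grid; the head is a 1×1 convolution with a sigmoid.
Hidden activations are ELU (avoids dead units and vanishing gradients at
these small widths); dropout at rate 0.125 follows every convolution and is
active only during training. With the defaults this network has 485,673
trainable parameters; at 64 base filters (the classic layout) it has
31,030,593.

Choices the architecture description leaves open, fixed here: depth 4
(bottleneck 128 channels at the default width), 2×2 transposed-convolution
kernels, and "same" padding (required for like-sized input/output). All are
exposed in `NetworkConfig`.

The implementation is pure NumPy (`organotrack.nn`): im2col convolutions,
argmax-tracked pooling, einsum transposed convolutions, hand-written backward
passes, He-normal initialisation, and Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-7).
Correctness is guarded by finite-difference gradient tests on every layer and
on the assembled network. Activations are float32; losses are accumulated in
float64. Binary cross-entropy is computed from logits with the
`max(z,0) − zt + log(1+e^{−|z|})` form, so saturated outputs cannot overflow.

### Preprocessing

Images are contrast-normalised by rescaling the 1st–99th intensity
percentiles to [0, 1] with clipping (robust to hot pixels; the percentile
choice is a documented convention), then resized bilinearly to
`input_size × input_size` (default 512). A constant image maps to all zeros
rather than dividing by zero. At inference the sigmoid output is resized
bilinearly back to the source grid, so every downstream pixel-area parameter
(notably the 200-px minimum) operates in original-image pixels.

### Training

Adam at learning rate 0.001, batch size 8 (paired-transform augmentation —
random rotation, zoom 0.9–1.1, shear ±0.15, and an elastic displacement
field of ~12 px amplitude smoothed at σ = 8 — can expand a small training set
to `augmented_count`, default 2000). Early stopping monitors validation loss:
the untrained model's validation loss is evaluated once as an epoch-0
baseline, and training halts after `max(patience, 1)` consecutive epochs
without strict improvement (default patience 10); the weights of the best
validation epoch are restored. The baseline evaluation makes the rule
well-defined at patience 0 and lets a training run that never improves
return the initial weights honestly. All stochastic steps (initialisation,
dropout, shuffling, augmentation) flow from explicit seeds.

## Identification

Pipeline on a probability map `p`:

1. mask = `p > 0.5`, then morphological opening with a radius-1 disk
   (removes sub-element speckle without eroding organoids near the 200-px
   floor; the structuring element is a documented choice),
2. edges = hysteresis threshold (high 0.05, low 0.005, in units of
   probability per pixel on the raw gradient) of the Gaussian-smoothed
   (σ = 2 px) Sobel gradient magnitude of `p`,
3. seeds = 8-connected components of `mask AND NOT edges`; components under
   10 px are dropped so noise fragments cannot split one organoid into two
   basins (the floor is a documented choice; edges are not dilated before
   subtraction),
4. watershed on `−p` restricted to the mask, with the seeds as basins; each
   label is then morphologically filled (per label, not on the union),
5. labels with area strictly below `min_area` = 200 px are discarded (area
   exactly 200 survives); labels touching the border are discarded by
   default (`remove_border`); survivors are renumbered 1..k by decreasing
   area, ties broken by the raster position of the topmost-leftmost pixel.

The whole pipeline is deterministic: identical inputs give bit-identical
labelings.

## Tracking

For each frame, a cost matrix pairs active tracks (rows, represented by their
last-seen pixel masks) with current detections (columns): cost = 1/overlap
for pairs sharing pixels, a prohibitive 10·`pad_cost` for pairs sharing none.
The matrix is padded to square with pseudo-assignment rows/columns at
`pad_cost` (default 1.0 — the cost of a 1-pixel overlap, the natural scale of
the 1/overlap cost) and a free pad×pad corner, so any organoid can opt out.
`scipy.optimize.linear_sum_assignment` solves the assignment; matched pairs
with zero overlap are treated as non-matches. Unmatched detections open new
tracks; unmatched tracks are recorded MISSING and retire after `max_missing`
(default 1) consecutive missed frames. Track ids are never reused. Whether
organoids may reappear after an absence is governed entirely by
`max_missing` rather than hard-coded.

## Measurement

Perimeters use scikit-image's weighted contour-step estimator; naive
pixel-edge counting overestimates perimeters and biases circularity low by up
to ~27% for disks. Circularity is `4πA/P²`, clipped at 1 against residual
rasterisation bias (a rasterised r = 30 disk measures ≈ 1.0). Solidity and
eccentricity come from the region's convex hull and second central moments.
Cohen's *d* pools the two group variances with n−1 denominators. The 4PL fit
runs in log-dose parameterisation with EC50 bounded in
[min dose/10, max dose·10], three starts (hill +1, −1, +3), and reports
`converged=False` when the residual sum of squares fails to undercut 95% of
the response variance (flat or non-sigmoidal data) — asymptotes are returned
in canonical `bottom ≤ top` order. Lin's CCC confidence intervals use the
Fisher z-transform with Lin's (1989) variance. Empty-vs-empty IOU is defined
as 1 (no organoids, correctly predicted none). Tracking accuracy aligns the
two tables' arbitrary track ids by a Hungarian matching on agreement counts
before scoring each frame.

## Synthetic fixtures

`organotrack.synth` generates scenes of radially perturbed ellipses
(harmonics k = 2–4, amplitude up to `boundary_irregularity`, so circularity,
solidity and eccentricity vary meaningfully): an intensity image (darker
textured interiors on a brighter background with an illumination gradient,
dark rims, iid sensor noise `noise_sd` = 0.02, optional bubble-ring and
debris distractors), exact instance labels, and a probability map with
`interior_level` = 0.9 inside, `background_level` = 0.05 outside, and a
`valley_width` = 2 px band at `interior_level − valley_depth`
(default depth 0.5) along every contact line between touching organoids —
the reduced-confidence boundary the identification pipeline exploits.
Probability-map noise is modelled as smooth, spatially correlated confidence
ripple (sd 0.005, correlation 4 px), not per-pixel noise: a sigmoid network
output is saturated and smooth, and its flat-region gradients must sit below
the hysteresis low threshold for the edge detector to be meaningful. Pushing
`prob_noise_sd` toward ~0.02, `valley_depth` below ~0.1, or drift beyond the
frame-to-frame overlap scale makes identification or tracking fail — the
knobs deliberately span the method's working range.

Touching pairs are constructed by stepping the second organoid inward along a
random direction until the rasterised masks first overlap, so pairs abut with
~1-px contact and neither shape is swallowed. Time-lapses drift each organoid
by a per-frame random-walk step (default 2 px), grow the axes by
`growth_rate` per frame (default 2%), honour disappearance/appearance
schedules, and paint per-identity exponential fluorescence; placement
reserves clearance for the full growth and drift budget.

What the generator does *not* emulate: microscope optics (defocus, halos,
uneven illumination beyond a linear gradient), organoids overlapping across
focal planes, out-of-focus motion, annotation noise, or the intensity
statistics of any specific organoid type. Passing fixture tests therefore
demonstrates the correctness of the algorithms under their stated assumptions
(thresholdable foreground, reduced boundary confidence, frame-to-frame pixel
overlap), not segmentation accuracy on real brightfield data — the published
real-data benchmarks (test IOU, count/area CCC, 89% tracking accuracy, EC50
agreement with an MTS assay) require the external microscopy dataset and are
optional replication targets, not part of this test surface.

## Problem sizes

The test suite trains a scaled-down detector (4 base filters, depth 3,
128×128 inputs, 50 training scenes, ≤10 epochs, batch 2 — ~390 Adam steps)
once per session and reuses it; on one CPU core this takes ~25 s and reaches
held-out IOU ≈ 0.96 on the synthetic task, far above the conventional 0.5
benchmark. Identification fidelity is measured on 50 seeded 512×512 scenes
with 5–20 organoids and up to 4 touching pairs; assignment optimality against
brute-force permutation minima uses 1,000 random matrices up to 6×6; tracking
uses 20-frame time-lapses with one disappearance and one appearance; EC50
recovery uses 100 replicate fits at 5% multiplicative noise. These sizes were
chosen so the whole suite completes in about a minute while every statistic
is estimated from a population rather than a single draw.

## Known limitations

* A pixel belongs to at most one organoid: structures overlapping across
  focal planes are not separated.
* The NumPy trainer is single-threaded BLAS-bound; it is intended for the
  compact default architectures, not for large-scale GPU training.
* Tracking uses pixel overlap only (no motion prediction or appearance
  features) and models no division/merge events.
* The hysteresis thresholds are calibrated for probability maps; applying
  identification to raw intensity images is unsupported.
* Several inconsistent verbal definitions of circularity circulate in the
  organoid-morphometrics literature (perimeter-ratio vs. area-ratio
  phrasings); `4πA/P²` is the standard form and the one implemented, and
  shape-metric comparisons against other tools should confirm the variant
  used.
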