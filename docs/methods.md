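# Methods

## The measurement model

A stained vessel section is modeled as an annular wall of two intermixed
tissue classes — reddish smooth-muscle fiber (SMF) and blue/green
extracellular matrix (ECM) — surrounded by a bright near-white background
and lumen, possibly contaminated by dark tissue folds, blood residue and
dust.  The quantity of interest per image is the pair of normalized areas
`Ā_SMF = A_SMF/A_TOT`, `Ā_ECM = A_ECM/A_TOT`, where all areas are pixel
counts (no µm calibration; magnification is assumed constant within a
study, so ratios are comparable across samples).

All color reasoning happens in CIELab (sRGB primaries, D65 white point,
L\* in [0, 100]), whose Euclidean distance approximates perceptual color
difference; this is what makes a single k-means distance threshold work
across the stain-intensity variation seen between samples.

## Pre-processing

1. **Fold removal.** Folds are much darker than either tissue class.  The
   L\* histogram (101 bins over [0, 100], moving-average smoothing with
   window 5) is scanned from 0 upward; the first peak whose smoothed
   height reaches 25% of the global maximum is the "first predominant
   peak" (in practice the wall tissue, with background/lumen peaks
   further right), and the fold threshold is half its location.  Runs of
   equal smoothed height are treated as one plateau located at its
   center, so a histogram spike smeared by the smoothing window still
   yields the spike position.  Pixels with L\* below the threshold are
   defects.
2. **Blood removal.** Blood shares hues with SMF, so it is removed by an
   explicit color mask: a sphere in Lab space (default center
   (35, 45, 25), radius 12).  The defaults are tuned to the synthetic
   generator's blood color and are plain config values for real data.
3. **Defect handling.** Defect pixels are zeroed in L\* *and* flagged
   invalid.  The invalid flag is what matters downstream: the
   contrast-stretch extrema and the Otsu histogram are computed over
   valid pixels only, otherwise the injected zeros would pin `Lmin = 0`
   and distort both.
4. **Contrast stretch.** `round(100·(L−Lmin)/(Lmax−Lmin))` over valid
   pixels; monotone, endpoints map to 0 and 100.  A constant raster is an
   error (nothing to stretch — blank image).
5. **Otsu binarization.** The stretched lightness (scaled to [0, 1]) is
   quantized to 256 levels and the split maximizing between-class
   variance is found by exhaustive search using exact integer
   arithmetic — the score comparison is done by cross-multiplication of
   integer numerators/denominators, so the argmax is bit-deterministic
   and ties resolve toward the lowest threshold.  The returned T is the
   decision boundary `(k+0.5)/255` between quantized levels; the wall is
   the dark class (`value ≤ T`).
6. **DBSCAN cleanup** (defaults R = 3 px, MinPxs = 9, Euclidean distance
   on pixel centers, points visited in row-major order so the labeling is
   deterministic).  Two passes: (a) cluster the foreground and keep only
   the largest cluster — everything else is dust/dirt; (b) cluster the
   remaining non-wall pixels and keep the two largest clusters (exterior
   and lumen), merging every other non-wall cluster or noise pixel back
   into the wall, which fills interior pinholes.  When folds sever the
   ring visually, the 2-px fold width keeps the wall density-connected at
   R = 3, so pass (a) does not drop wall arcs.

`A_TOT` is the pixel count of the cleaned wall mask.

## Feature extraction

Pixels outside the wall — and defect pixels inside it — are painted white,
and the whole image (wall plus white background) is clustered with k-means
at k = 3 on (stretched L\*, a\*, b\*).  The cost is
`J = Σ_j Σ_i ‖px_ij − centroid_j‖`, a sum of *unsquared* Euclidean
distances, used as the convergence monitor (stop when the relative change
drops below 1e−4, cap 300 iterations) and as the model-selection score
across 10 random restarts (centroids initialized at distinct pixel
colors).  Centroid updates are per-group color means.  Because the mean
minimizes squared rather than unsquared distance, J is not theoretically
guaranteed to decrease at the update step; on color-separated histology
data it does in practice, and the recorded per-iteration trace is checked
in the tests.  An emptied cluster is re-seeded at the pixel farthest from
its assigned centroid.

Roles are assigned by rule: the cluster whose centroid is nearest white is
background; of the remaining two, the larger-a\* (redder) centroid is SMF.
Ties break toward the lower cluster index with a logged warning.
`A_SMF`/`A_ECM` count the role-mapped cluster pixels inside the wall mask,
so `Ā_SMF + Ā_ECM ≤ 1`, with the slack taken up by defect and
background-classified pixels inside the wall.

Clustering is per-image (each image gets its own centroids), which is what
makes the measurement robust to stain variation between samples.

## Permutation statistics

Two groups of normalized areas are compared by pooling and resampling
without replacement: m pseudo-assignments of the pooled values into groups
of the original sizes, statistic T recomputed each time (mean difference
by default; median difference and the two-group one-way F are options).
With b resamples at least as extreme as observed, `p = (b+1)/(m+1)`; the
+1s keep p strictly positive and give a resolution of 1/(m+1).  "At least
as extreme" means `|T_perm| ≥ |T_obs|` two-tailed (the default) or
`T_perm ≥ T_obs` one-tailed; ties count, and a 1e−12 relative slack in the
comparison keeps genuine ties from being dropped to floating-point
summation-order noise.  The total assignment count `(n1+n2)!/(n1!·n2!)` is
computed exactly; an exhaustive enumerator covers instances up to 10⁶
assignments and serves as the small-sample oracle.

Uncertainty of the Monte-Carlo estimate is reported as a binomial
confidence interval: by default the normal approximation
`p̂ ± z·sqrt(p̂(1−p̂)/m)` clipped to [0, 1] (z = 1.959964 at 95%), with
Clopper–Pearson as an exact option.

**Reproducible parallelism.** m is split into fixed 10,000-resample
chunks; chunk i draws from `default_rng([seed, i])`, an independent
substream, and the exceedance counts are summed.  The result is therefore
a pure function of (data, m, statistic, tail, seed), identical for any
worker count or scheduling.  Internally the pooled array is arranged in a
canonical group order (orientation restored for signed statistics), so a
two-tailed result is also bit-identical under swapping the group labels.

No multiple-testing correction is applied across the pairwise group
matrix; with three groups and two components there are six tests, and
consumers should account for that when interpreting borderline p-values.

## Synthetic data

`generate_vessel_image` renders what the pipeline assumes: a 160×160
image, wall annulus with inner/outer radii 28/60 px (≈8.8k wall pixels),
background L\* = 96, SMF/ECM palettes (55, 35, 15) / (60, −20, −15),
blood (35, 45, 25), per-channel Gaussian Lab noise of sd 3, two 2-px dark
fold chords, three blood blobs (radius 3–6 px) inside the vessel, and
fifteen 1–5 px dust specks in lumen/exterior.  The SMF/ECM split is a
smoothed random field (σ = 6 px) thresholded at the quantile matching the
requested fraction, producing connected blotches and a realized fraction
within ±0.01.  Ground-truth masks partition the image exactly.

What it does *not* emulate: uneven illumination, stain-batch hue drift
beyond a global offset, partial-volume mixing at class boundaries,
out-of-focus blur, layered wall anatomy (intima/media/adventitia), or
realistic fold geometry.  Passing the recovery tests therefore shows the
algorithmic chain is correct and well-calibrated under its stated
assumptions, not that it segments any real slide correctly; on real data
the blood-mask color and DBSCAN scale need checking against a few
annotated samples.

`generate_group_samples` draws per-sample ratio tables from truncated
normals on [0, 1] with per-group means — a fast cohort stand-in for
exercising the statistics stage without rendering images.

## Problem sizes in the test suite

Parameter-recovery tests run the full pipeline on 160×160 images over
true SMF fractions {0.2, 0.4, 0.6, 0.8} × 10 seeds (mean absolute error
bound 0.05).  The Monte-Carlo engine is checked against exhaustive
enumeration on 200 random instances with group sizes ≤ 6 at m = 20,000
(3-binomial-SE tolerance), and its type-I error is calibrated on 1,000
null replicates of two n = 20 groups at m = 2,000 (rejection rate within
[0.03, 0.07] at α = 0.05).  Otsu and DBSCAN are verified against naive
exhaustive/all-pairs oracles on ≤64×64 rasters and 40×40 masks.

## Known limitations

- Areas are in pixels; cross-study comparability requires equal
  magnification.
- The fold threshold assumes folds are darker than half the first tissue
  peak; faint folds pass through and are then attributed to a tissue
  class by color.
- The background/SMF/ECM role rule assumes exactly one near-white
  cluster; heavily stained images with no visible background would need
  k or the rule adjusted.
- The two-pass DBSCAN cleanup keeps the two largest non-wall regions;
  images where folds connect lumen and exterior into one region retain a
  second small region harmlessly, but a wall fragmented into disconnected
  arcs wider apart than R is truncated to its largest arc.
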