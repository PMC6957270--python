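# Methods

This note records the model, the numerical and design choices behind
`signalscan`, and what the synthetic validation does and does not
demonstrate.

## Classification model

The classifier is the "average face model" of species face learning: a
receiver is assumed to encode each species' face pattern as the mean of
encountered examples and to compare a new face against those means in a
low-dimensional perceptual face space.

Averaging is two-stage everywhere: images → individual average → species
average. Individuals therefore contribute equally to their species average
regardless of how many photographs each has; a well-photographed individual
cannot dominate its species' template. The same two-stage rule applies when
binary occlusion maps are aggregated into heatmaps.

PCA is taken over the species average faces (not raw images), so the
eigenfaces span exactly the between-species variation: at most
`n_species − 1` components, computed by thin SVD of the centered
`n_species × D` matrix (equivalent to the small Gram-matrix eigenproblem;
`D = H·W·3` never enters the decomposition cost). Components with variance
below `1e-10` of the leading component are dropped as numerical zeros. Sign
convention: the largest-magnitude element of each eigenface is positive, so
serialized bases are reproducible. Pixels are float64 in [0, 1] throughout.

Classification is nearest species centroid by exact Euclidean distance in
weight space; ties (exact or within 1e-12 relative) go to the earlier
species in the manifest's species order and are flagged. An exemplar-model
alternative (nearest individual-average, majority vote) is provided as
`classify_exemplar` but is not used by the pipeline; prior work found the
two models give very similar results.

Leave-one-out evaluation is by individual, not by image: all of an
individual's images leave the training set together, and the entire model
(averages, grand mean, eigenfaces, centroids) is rebuilt per fold. The fold
models are cached on the evaluation result so the occlusion scan can reuse
exactly the model that classified each image. Reported accuracy comes in
two denominations: distinct images (one unit per photograph) and
individual averages (one unit per individual). Hemi-face analyses rerun
this entire pipeline independently per side; the left side is the default
reporting configuration, with right-side agreement treated as a
qualitative check.

## Occlude-reclassify scan

The occluder is a closed disc on the integer lattice (`dr² + dc² ≤ r²`,
boundary included), stride 1 px, filled with the per-channel mean color of
the species average face *from the training fold of the scanned image* —
so the fill color, like everything else, never sees the held-out
individual. Only centers at least `r` from every border are tested (the
full disc must fit); untested border cells are marked explicitly, never
imputed. At the published scale (radius 30 on a 196×297 hemi-face) the disc
covers 2821 pixels, 4.85% of the image.

Acceleration: occluding at center `p` changes the image only inside the
disc, so the change in eigenface weight `j` is

    Δw_j(p) = Σ_{q ∈ disc(p)} e_j(q) · (fill − y(q)),

a correlation of the (symmetric) disc kernel with the per-pixel inner
product map `Σ_c e_j(·,c)·(fill_c − y(·,c))` — one FFT convolution per
eigenface yields every center's weights at once, `O(k·HW·log HW)` instead
of `O(HW · r² · k)`. The naive occlude→project→classify path is retained
and the test suite verifies exact classification agreement and weight
agreement within 1e-9 at every tested center on 64×64 instances (FFT
round-off is ~1e-12 here). Distances to centroids never need the image
dimension: classification of all centers is a `(centers × k)` against
`(species × k)` comparison, with first-minimum tie-breaking identical to
the scalar classifier.

## Metrics

`proportion_misclassified` counts heatmap cells strictly below 1 over
*tested* cells. The strict test is exact: heatmap values are two-stage
means of small integer counts, and a cell equals 1.0 exactly when every
contributing map is correct there. The denominator excludes the untested
border: those cells were never evaluated, so including them would dilute
the proportion by an arbitrary border area (the metric is then invariant
to padding, which the tests assert).

`mean_classification_error` is the mean of `1 − value` over critical
cells, so higher = more essential, matching the heatmap convention that
darker (lower fraction-correct) regions matter more. The raw mean of the
heatmap values over critical cells is emitted alongside
(`mean_value_critical_raw`) since the two orientations are both in
circulation; they sum to 1.

Composite renderings blend a colormapped heatmap over the greyscale
species average (`alpha·cmap(h) + (1−alpha)·grey`, default alpha 0.5,
Rec. 709 luminance, perceptually uniform `viridis` by default; the
colormap is a display choice only and enters no metric).

## Standardization choices

Images are H×W×3 float64 in [0, 1]; integer rasters are scaled by their
format maximum. The standard face is 392 wide × 297 high: the hemi-face
split is along the vertical facial midline, which requires an even width
(392/2 = 196), and the deposited-database orientation should be checked on
first use. Resizing uses area (box) interpolation when downscaling — it
preserves mean level, verified against explicit block averaging — and
bilinear otherwise; the method used is recorded in the record's metadata.
The RGB→LMS (cone-excitation) transform is a per-pixel 3×3 matrix supplied
via config; the default is the identity because the camera-specific
calibration matrix belongs to the image-acquisition pipeline, not this
package. Alignment and background segmentation are assumed already applied
to inputs.

## Synthetic validation data

The generator emulates the *structure* of a standardized face-image
database: a shared, shaded oval base face; species defined by localized
color features (discs, bars, arcs); several individuals per species with
per-individual feature contrast jitter (±15% by default); several images
per individual with per-image Gaussian pixel noise (sd 0.02, clipped to
[0, 1]). All randomness flows from a single seeded generator, and the
recorded ground truth is the pixel mask of each species' unique features
(a feature shared verbatim between species is diagnostic of neither).

Positional jitter of features is available but defaults to 0: the emulated
databases are landmark-aligned and size-standardized, so residual
positional variation is small, and the alignment step itself is out of
scope here. Contrast jitter and pixel noise carry the within-species
variation instead.

The default specification is desk-scale so the full pipeline runs in
seconds: 4 species × 4 individuals × 3 images at 64×64, occluder radius 6
(the same radius-to-width ratio as 30/392). Its species were designed so
that the attribution geometry is analytically predictable from feature
"masses" (squared contrast × area, the squared pixel-space distance a
feature contributes between centroids):

* `nosespot` — one bright disc (mass ≈ 30). Occluding most of it leaves the
  image nearest the near-featureless species, so exactly the nose region is
  flagged, deeply.
* `browcheek` — a bright brow bar (mass ≈ 43) plus a moderate cheek disc
  (mass ≈ 18) in disparate regions. Covering the bar outweighs the
  remaining cheek (flip to the plain species); covering the cheek leaves
  the image nearer the brow-only near-twin. Both regions are flagged, so
  the critical region is wider but individual flips are shallower than the
  nose spot's.
* `browplain` — a brow bar nearly identical in color to `browcheek`'s plus
  a faint arc tuft (mass ≈ 5). The pair tests discrimination between
  similar species; the tuft is too weak for its occlusion to flip anything.
* `plainface` — a tiny dim spot (mass ≈ 0.15). Recognized by the *absence*
  of traits: no single occlusion can make another species' image out of
  it, so its heatmap is expected to be clean — the negative-space case.

A flip under occlusion requires the covered mass to exceed the species'
remaining distinctive mass plus the nearest alternative's; this is why a
species with two comparable, redundant traits is hard to break with one
disc, and why the designed masses are deliberately asymmetric.

What passing the synthetic tests shows: the pipeline recovers known
diagnostic-feature locations (flagged cells fall inside the ground-truth
mask dilated by the occluder radius, hit fraction ≥ 0.9 for the
single-trait species across seeds), separates concentrated from
distributed signals (the two-trait species has strictly larger
proportion_misclassified), and degrades monotonically with pixel noise.
What it does not show: robustness to misalignment, illumination and pose
variation, soft-edged or textured natural markings, or correlated
photographic noise — real faces are not ovals with painted patches, and
performance claims on natural images rest on the database benchmarks, not
on the generator.

## Problem sizes and determinism

The test suite and the acceptance script run entirely at the desk scale
above (48 images; full scan of all correct images in a few seconds;
recovery repeated over 5 seeds). Published-scale runs (599 images, 133
individuals, 15 species; radius 30) use the identical code path:
classification in minutes, the full occlusion scan 1–3 h on one CPU with
the convolution acceleration. Repeated runs with identical inputs and
configuration are bit-identical; pipeline artifacts embed a hash of the
serialized configuration and the summary reporter refuses mismatched
directories.

## Known limitations

* The classifier is deliberately simple (nearest centroid in a linear
  subspace); it is a model of signal content, not a best-possible species
  classifier.
* Occlusion attribution is single-disc: pairs of regions that are jointly
  but not individually necessary (redundant signals) are not flagged, by
  design of the method.
* The sympatric species subsets are shipped as fixed presets; range-map
  computation is out of scope.
* Heatmap comparison across species is visual/metric-based; no statistical
  test between heatmaps is provided.
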