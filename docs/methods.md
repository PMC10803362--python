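# Methods

## Overview

`viadens` quantifies treatment response in resected tumors as the density
of viable tumor cells per mm² of annotated tumor area and asks whether a
density cut-off stratifies survival. The pipeline has three stages —
detection, density, survival — plus a synthetic-data module that provides
exact ground truth for all of them. Everything below is desk scale: it
runs on one CPU in minutes.

## Detection: heatmap regression from point annotations

Ground truth for nucleus detection is a point per viable nucleus, not a
mask. Points are converted to a continuous regression target: one
isotropic Gaussian bump of peak amplitude 1 per point, σ = 6 px by
default (about a third of the ~20 px nucleus radius, so bumps stay inside
nuclei), combined by element-wise **maximum** rather than sum so that
overlapping nuclei cannot push the target above 1. The detector minimizes
mean squared error against this map using the Adam optimizer; after every
epoch the validation F-measure (matching radius 20 px) is computed and
the weights of the best validation epoch are adopted.

The regressor itself is a small multilayer perceptron (hidden layers
32/16) over a fixed multiscale feature bank: Gaussian-smoothed intensity
and gradient-magnitude features of the three color channels at dyadic
scales σ ∈ [1, 8] px (scikit-image `multiscale_basic_features`). This
per-pixel design was chosen for strict seeded determinism and CPU-scale
training; it has ample capacity for the color/texture contrast that
separates basophilic nuclei from pale debris. Encoder–decoder CNNs
(U-Net family) are the field-standard choice at production scale and the
configuration deliberately keeps their training protocol (epochs, MSE,
Adam, best-validation-epoch selection) so the detector backend can be
swapped without touching the harness.

Each training epoch is one shuffled minibatch pass over a balanced pixel
sample: all foreground pixels (target > 0.05) plus twice as many randomly
redrawn background pixels. Features are standardized by a scaler fitted
once on a 100k-pixel subsample. All randomness (sampling, shuffling,
weight init) derives from `DetectorConfig.seed`; two runs with the same
config are bit-identical.

Detected points are the local maxima of the predicted map with value ≥
`peak_threshold` (default 0.3), accepted greedily in order of descending
value — ties broken by (row, column) — suppressing any candidate within
`peak_min_distance_px` (default 20 px, the nucleus radius) of an accepted
stronger peak.

## Evaluation protocol

A detection is a true positive when it can be paired one-to-one with a
ground-truth point at Euclidean distance ≤ 20 px (inclusive; the radius
equals the approximate nucleus radius). Where several pairings are
possible, the maximum-cardinality pairing with minimal total distance is
used (Hungarian assignment with infeasible pairs priced out), making the
result deterministic and order-independent. Precision = tp/(tp+fp),
recall = tp/(tp+fn), F = their harmonic mean; the empty-vs-empty case is
defined as perfect (no errors were made), and 0/0 ratios with errors
present score 0. Cross-validation groups patches by patient into five
seeded subsets (optionally balanced on a stratification label such as
specimen type); each fold trains on three subsets, selects on one and
tests on one, rotating so every subset is tested exactly once. Fold
metrics pool tp/fp/fn over the fold's patches; the summary reports the
across-fold mean and sample standard deviation (ddof = 1).

## Density: Sum/Area over annotated regions

Slides are tiled by a fixed non-overlapping grid anchored at the raster
origin (stride = patch size; the upstream protocol states no overlap, and
non-overlap avoids double counting). A grid patch enters the workload iff
its rectangle intersects the tumor polygon with positive area. Patches
partially outside the region are processed whole, but detections are kept
only if they fall inside the polygon — boundary points count as inside
(documented tie rule) — because the area in the denominator is the
polygon area, so the numerator must be polygon-limited too. Detections
within 20 px of a stronger detection across adjacent patch borders are
deduplicated with the same greedy rule as peak extraction, preventing
double counting at seams. Area is the shoelace polygon area (holes
subtracted) × (mpp/1000)²; mpp (microns per pixel) is a required
calibration input — absolute densities are meaningless without it, and
the per-case density is the pooled ratio ΣSum/ΣArea over all slides of
the case, **not** the mean of per-slide densities.

## Survival: cut-off scan and selection

Patients are split at a density cut-off c into high (density ≥ c,
tie counts as high) and low groups. The scan evaluates c = 50, 100, …
up to the maximum observed density (floor(max/50) rungs): each rung gets
two-sided log-rank p-values for DSS and MFS, and is evaluable only when
both groups have ≥ 5 patients (the minimum prevents degenerate log-rank
fits at extreme cut-offs) and the tests are defined. Among evaluable
rungs significant (p < 0.05) on **both** endpoints, the selected cut-off
minimizes |n_low − n_high|, ties going to the smallest cut-off. No
multiple-testing correction is applied across the scan; this mirrors the
source protocol and is a known limitation of cut-off dichotomization, not
an oversight. Hazard ratios come from univariate Cox regression (Efron
tie handling, Wald 95% CI); monotone likelihood (all events in one group)
is detected up front and flagged instead of letting the fit diverge.
The density-vs-necrosis cross-tabulation dichotomizes necrosis at ≥ 90%
(grades III–IV) and reports the fraction of poor-necrosis cases that the
density method nevertheless calls low-density. Distribution comparisons
(e.g. re-stained vs original specimens) use the two-sided Mann–Whitney
test: exact enumeration when both samples have ≤ 10 untied observations,
tie-corrected normal approximation otherwise.

## Synthetic data: what it emulates, and what it does not

**Patches** emulate the salient decision contrast of H&E at high power:
viable nuclei are dark, hematoxylin-colored filled ellipses (eccentricity
0.6–1.0, random orientation, color jitter) of radius ~20 px; distractors
are pale low-saturation fragmented clusters standing in for necrotic
debris and stroma; the image is softened (σ = 1.2 px) and Gaussian noise
added. Placement is rejection sampling with at most 1000 retries per
point: viable centers keep the full `min_separation_px` (default 45 px)
from each other so ground truth is unambiguous and seam deduplication
cannot merge two true cells, while distractors only keep 2r + 2 px off
viable blobs and may cluster among themselves, since uniform separation
for all points exceeds the random-packing limit at realistic counts.
**Slides** plant nuclei uniformly inside an arbitrary tumor polygon at
the patch spec's areal density (or an exact requested count); the planted
density is recoverable from the returned fields with no rendering loss.
**Cohorts** draw density from a two-component Gaussian mixture; patients
at or above `true_cutoff` have their exponential event hazard multiplied
by `hazard_ratio_high` for both endpoints, with one exponential censoring
time per patient truncated at the follow-up horizon. Necrosis response
links stochastically to the density group (defaults P(≥90% | low) = 0.4,
P(≥90% | high) = 0, so discordant cases exist). Times are in months.

Two generator choices matter for interpretation. First, mixture
components have **fixed sizes** (round(w·n) patients per component,
shuffled): with i.i.d. membership, binomial noise in component counts
moves the cohort's median away from the planted cut-off, and the
balance-based selection rule then tracks that noise rather than the
planted truth. Second, the default mixture is **symmetric about the
cut-off** (means 150 and 650, both σ = 100, weight 0.5): the selection
rule can only identify a cut-off that is also the cohort's balance point,
so a recoverable planted cut-off must be the population median. Both are
properties of the selection rule, not of the implementation; asymmetric
cohorts can be generated, but their planted cut-off need not be
recoverable by balance.

Passing tests on this synthetic material establishes that the machinery
is correct — targets, matching, geometry, pooling, statistics — under
conditions where truth is known exactly. It does **not** establish
detection performance on real H&E: no staining variation, section
artifacts, nuclear pleomorphism, touching nuclei or scanner noise are
modeled, and the photometric gap between viable and necrotic cells is far
cleaner than in tissue.

## Problem sizes and numerical choices

Default desk-scale conditions: 256×256 px patches (1024 is the
production patch size and remains configurable), ~10 nuclei per patch,
training sets of a few dozen patches, 3–8 epochs (the production
protocol trains 1000), 4×4-tile pseudo-slides at 1 µm/px, cohorts of
200–400 patients for recovery experiments and 200 replicates for null
calibration. Tolerances used in the test suite: Gaussian-integral check
1%, polygon area vs rasterization 0.5%, trained-detector density
recovery 10%, log-rank size 0.05 ± 0.03, cut-off recovery ± one 50/mm²
step. Tie rules (density ≥ cut-off is high; boundary points are inside;
peak ties by row then column; selection ties to the smallest cut-off)
are each asserted by a dedicated test.

## Known limitations

- The detector is a per-pixel regressor over fixed features; on real
  tissue a learned convolutional encoder–decoder would be expected to
  dominate it, and the package treats the backend as swappable.
- Absolute densities depend entirely on the µm/px calibration; no
  default magnification is assumed correct for any particular scanner.
- The cut-off scan performs no multiplicity control, and the selection
  rule is identifiable only when the true cut-off balances the cohort.
- Survival generation uses exponential baselines and independent
  endpoints; real DSS and MFS are correlated within patients beyond the
  shared censoring time used here.
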