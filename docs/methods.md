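# Methods

This note documents the models, conventions and numerical choices behind
`iapsmon`, and what the synthetic test surface does and does not show about
real surveys.

## Acquisition geometry model

The planner treats the roadside as a vertical plane at working distance WD
from a pinhole camera with horizontal field of view HFOV and N horizontal
pixels, driven at speed v with exposure time t and camera yaw φ (0 =
perpendicular to driving).

* Footprint width on the roadside plane at φ = 0: `2·WD·tan(HFOV/2)`.
* Centre-pixel GSD: `GSD(φ) = GSD(0)/cos²φ` with
  `GSD(0) = 2·WD·tan(HFOV/2)/N`. One cosine accounts for the longer slant
  range `WD/cosφ`, the other for the oblique pixel footprint on the plane.
  This is a model choice — a thin-lens, distortion-free approximation — and
  it gives the expected behaviour: finest GSD and smallest object-scale
  variation at the perpendicular orientation.
* Motion blur: the ground displacement `v·t` projected perpendicular to the
  line of sight (factor cosφ) divided by the GSD at slant range (a second
  cosφ): `blur(φ) = v·t·cos²φ/GSD(0)`. Blur is maximal at φ = 0 and linear
  in both v and t. For a 46° HFOV, 4000 px rig at 7 m, 110 km/h and
  1/1000 s this is 20.6 px — the regime in which leaf-scale texture is
  destroyed, which is why sub-millisecond exposures are used.
* Coverage arithmetic: `images/km = round(1000/coverage)`,
  `min frame rate = (v/3.6)/coverage`, `geotag gap = (v/3.6)/gps_rate`.
  Coverage-per-image is an **independent input** (the hardware-measured
  footprint), not derived from the FOV formula: measured footprints include
  lens distortion and calibration effects the thin-lens formula omits (for
  the reference rig, 6.2 m measured vs 5.94 m computed at 7 m). Default
  pixel count is 4000 (a 12 MP 4:3 sensor); the true sensor geometry of any
  given rig should be passed in.
* Display rounding only: 0.1 m for distances, 0.01 FPS, integer images/km;
  all internal values are full precision. Lens distortion and
  rolling-shutter skew are deliberately not modelled.

## Spatial clustering and the χ²-balanced split

Images closer than 40 m (haversine distance on a 6371 km sphere) are merged
by single-linkage transitive closure; the implementation uses a KD-tree on
a local equirectangular projection to find candidate pairs and confirms
each with the exact haversine distance, so it equals the brute-force
closure (tested against a BFS oracle). The 40 m default sits above the
worst-case 36.1 m geotag gap at 130 km/h and 1 Hz GPS, so consecutive
images of one patch always chain. Consumer-GNSS error (~2.5 m) is ignored
as small against the threshold. Opposite carriageways can fall inside 40 m
and are deliberately not disambiguated.

Cleaning removes, in order of attribution: multi-species images (ambiguous
classification targets), images with an annotation pair above 0.75 IoU
(ambiguous detection targets), then images of classes left with fewer than
30 images (default) dataset-wide. The rare-class count is taken after the
first two rules, which makes the operation idempotent. Polygon areas and
intersections are exact polygon geometry in pixel units; out-of-frame
vertices are clipped on load with a warning.

The split assigns whole clusters, never images. Targets are
`E_c(s) = fraction(s)·N_c` with `N_c` the dataset-wide image-class count —
chosen so the three targets sum to the full dataset. Clusters are shuffled
once with a recorded seed (one PRNG stream), then each is added to the set
whose `χ² = Σ_c (O_c − E_c)²/E_c` (classes with `E_c = 0` excluded)
decreases most; ties prefer train > validation > test; if no set improves,
the cluster falls back to the training set, and the step is flagged in the
assignment log so the non-increase property can be audited after the fact.
Per-image classes (not polygon counts) drive the balancing, since set sizes
are defined in images. Cluster "weights" are exactly these per-cluster
class-count vectors; no additional weighting is applied.

Class balancing repeats each minority class's images cyclically, in input
order, up to the majority-class count — deterministic, and the set of
distinct images is unchanged.

## Metric conventions

Two precision conventions are explicit flags, because they answer different
questions:

* `classification`: `P_c = TP_c / column_c`, `R_c = TP_c / row_c`,
  accuracy = trace/total. Macro averages are unweighted means over classes
  (optionally a subset); undefined per-class values (empty row/column) are
  NaN and excluded from macros with a warning.
* `detection-background-fp`: a detection of the wrong species still found a
  plant, so only detections on unannotated material count as false
  positives: `P_c = TP_c / (TP_c + FP_background,c)` where
  `FP_background,c` is the background row of column c. Micro averages pool
  counts: `P = ΣTP/(ΣTP + Σ background FP)`, `R = ΣTP/Σ annotated`, and the
  summary F1 is their harmonic mean. This convention was verified
  cell-by-cell against the bundled published detection matrix and its
  printed metric table (all per-class values and the micro row reproduce
  exactly after 3-decimal rounding; the one printed F1 that disagrees with
  the harmonic mean of its own printed precision/recall, 0.569 vs 0.596,
  is a transposition misprint and the harmonic mean is used).

F1 is always the harmonic mean of the same report's precision and recall.
Merging to invasive vs non-invasive sums all (species, species) cells into
the invasive-invasive cell, forgiving inter-species confusion; totals are
preserved.

Size-binned recall buckets images by combined annotation area divided by
image area (capped at 1), default 10 equal bins on [0, 1]; the smoothed
curve is a Nadaraya–Watson Gaussian kernel regression of the per-image
correctness indicator on relative area, bandwidth 0.05 relative-area units
(configurable). Smoothing of a binned recall curve is under-determined in
general; kernel regression was chosen because it is the estimator whose
bin-width → 0 limit the raw curve approximates, and the raw per-bin recall
is always reported alongside. Grid points further than 4 bandwidths from
every sample are NaN rather than extrapolated.

Cluster-level detection treats a plant cluster as found when at least one
of its invasive images is predicted as **any** invasive species
(invasive-merged correctness); within detected clusters, precision is
correct-invasive calls over all invasive calls, averaged over detected
clusters.

## Detection matching

How published surveys matched detector boxes to polygon annotations is
generally unstated, so the matching rule here is an explicit, configurable
artifact decision: greedy one-to-one matching in descending confidence
order, each detection taking the unmatched annotation (any species) with
the highest IoU ≥ 0.5, computed against the annotation's bounding box by
default (full polygon optional). Unmatched detections become background
false positives; unmatched annotations become misses. Darknet-format class
indices map to the alphabetical list of the six retained species unless a
names file says otherwise.

The colour-prototype baseline classifier (nearest centroid on the mean RGB
of the central crop) exists so the pipeline runs end-to-end on rendered
synthetic images; it is a smoke-test model with no pretension to realism.

## Synthetic survey generator

Defaults encode the reference survey conditions: 110 km/h, 1 Hz GPS,
6.2 m coverage per image, 4000×3000 px frames, 40 m clustering, 70/15/15
split. Images are geotagged from the nearest GPS fix, reproducing the
fix-quantised geotag gaps of a real logger (up to 36.1 m at 130 km/h);
`geotag="exact"` disables this. The bundled example scenario is a 12.2 km
straight motorway stretch with 60 single-species patches (10 per retained
species) spaced 200 m apart, 25–45 m long, mean relative annotation sizes
0.1–0.5, and patch-triggered capture with a ±30 m margin (emulating a
record button with a ring buffer). These numbers were chosen once so that
every class retains ≥ 30 images (the cleaning default) and ≥ 50 clusters
exist with comfortable inter-cluster gaps; they are conditions, not tuning
knobs. Combined annotation areas are Beta-distributed with the patch mean
and concentration 10; 1–3 polygons per image are laid in disjoint vertical
slots so synthetic annotations never overlap.

What passing tests on this surface shows: the bookkeeping, clustering,
splitting, metric and mapping machinery is correct under controlled truth.
What it does not show: anything about real plant appearance — no
photorealism, no motion blur or rolling shutter in rendered images, no
label noise in annotations, no GNSS jitter, and patches are single-species
and well separated, unlike tangled real verges.

The kernel-recovery check compares each empirical confusion cell with its
multinomial expectation within 3σ, restricted to cells with expected
variance ≥ 5 where the normal approximation is sound.

## Problem sizes and determinism

Tests and the acceptance script run the bundled 12.2 km scenario
(~900 images, 60 clusters) and dense 1.5–2 km strips for the law-of-large-
numbers checks (up to 10,000 images); the full pipeline completes in
seconds. Every stochastic component takes an explicit seed; the CLI records
seeds, fractions and a config hash in each output manifest, and re-runs are
byte-identical.

## Known limitations

* The GSD/blur model is thin-lens and distortion-free; measured footprints
  should be supplied for real rigs.
* The split balances image-class marginals only; it does not balance
  polygon counts or annotation sizes across sets.
* Greedy χ² balancing has no optimality guarantee; with few, large,
  heterogeneous clusters the 70/15/15 shares can drift by several points.
* Detection matching is one detection per annotation; a detector that tiles
  one large plant with several boxes is penalised with background false
  positives.
* Mapping assumes the prediction's image timestamp falls within the track
  span; predictions outside it are dropped with a warning, not
  interpolated.
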