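# Methods

## The analysis model

A colony micrograph is a merged RGB image in which the blue channel carries
the DAPI nuclear counterstain and the red channel the sarcomeric-myosin
(MHC) immunostain. The analysis assumes the stains separate cleanly into
their channels (no spectral unmixing is attempted) and treats each image as
a single 2D plane.

All intensities are normalized to [0, 1] by dividing by the bit-depth
maximum of the source file (255 or 65535), so thresholds are bit-depth
independent. Coordinates are 0-based (row, col), row 0 at top, everywhere.

### Segmentation

Each channel is processed as: grayscale morphological opening with a flat
disk of radius *R* (erosion then dilation; suppresses bright features
narrower than the disk, including debris specks and shot noise), strict
thresholding at *T* (foreground iff intensity > *T*), then 8-connected
component labeling. *R* and *T* are set independently per channel; dim MHC
staining is handled by lowering the red-channel *T*.

Numerical/convention choices, made once:

* the disk is the exact Euclidean disk (all offsets with distance ≤ *R*),
  not a decomposed approximation — chosen for reproducibility across
  platforms;
* threshold is strict (>), so *T* = 0 cleanly means "any signal" and
  *T* = 1 an empty mask;
* foreground connectivity is 8-connected; regions touching the image
  border are retained (discarding them would bias colony totals);
* interior holes do not count toward a region's area;
* region boundaries are Moore-neighbor traces of the outer perimeter.

### Dataset-wide nuclear-size calibration

DAPI+ region areas from **all** images of a batch are pooled into one
histogram (default bin width 10 px²). The first (low-area) peak is taken as
the single-nucleus population; its arithmetic mean area is the divisor for
all out-of-peak regions:

* area within [lower, upper] → nuclear quantity exactly 1;
* any other area (smaller debris or larger clump) → area / mean, kept
  fractional. Rounding happens only at fiber classification.

The faithful operating mode is user-selected peak bounds, chosen by
inspecting the histogram (`calibrate` writes it as CSV and PNG). The AUTO
fallback smooths the counts with a 5-bin moving average, takes the first
local maximum scanning up from small areas as the single-nucleus mode, and
extends the peak to the nearest enclosing local minima (or histogram ends).
The 5-bin window was chosen over 3 because pooled area histograms are
spiky — rasterized disk areas are quantized, so neighboring bins alternate
between heavy and empty — and a narrow window lets the walk stop at a spike
notch inside the peak, truncating the genuine tail of the singles
population. A degenerate single-bin histogram yields that bin's span as the
peak, with a warning.

An optional `min_area` filter (default 0 = off) can discard sub-nuclear
debris outright; by default debris that survives the opening is counted
fractionally, exactly as the division rule dictates.

### Nucleus-to-cytoplasm mapping and metrics

A nucleus belongs to an MHC+ region iff its centroid — rounded to the
nearest pixel, halves toward the larger index — lands on that region's
label. Membership is a label-grid lookup, so assignment is independent of
enumeration order; a DAPI+ area that merely overlaps an MHC+ area without
containing its centroid stays stain-negative.

Per MHC+ region, member quantities are summed unrounded; the region is
classified by rounding that sum half-up: 0 → anucleate, 1 → mononucleated,
2 → binucleated, ≥ 3 → multinucleated (a definitive fusion product —
binucleated cells may merely be dividing). Per colony:

* D_f = 1 − stain_negative / total — fraction of nuclei within MHC+
  cytoplasm;
* U_i = Σ (quantities in multinucleated regions) / total — fraction of
  nuclei that have gone through a definitive fusion event.

U_i uses the rounded classification only for region *eligibility* and sums
unrounded quantities, so totals are conserved and U_i ≤ D_f always holds
(the sum is clamped at D_f to guard the one-ulp summation-order case). A
zero-nucleus image gets D_f = U_i = 0 with a logged warning rather than
NaN, keeping batch CSVs rectangular.

Group summaries are means with two-sided 95% Student-t intervals (n − 1
degrees of freedom; a single colony yields a degenerate interval with a
warning). Unpaired two-group comparisons use Welch's t-test, a robust
default when group variances differ.

### Batch driver

The dataset-wide calibration forces a two-pass design: pass 1 segments
every DAPI channel and fits the calibration from the pooled histogram;
pass 2 assigns quantities, detects MHC+ regions, maps centroids and writes
one CSV row per colony. Files are processed in lexicographic order (order
affects row order only); one unreadable file is logged and skipped without
aborting the batch. Each run writes fresh outputs so identical inputs and
configuration reproduce identical bytes.

Defaults: DAPI *R* = 2, *T* = 0.30; MHC *R* = 2, *T* = 0.25; AUTO
calibration; bin width 10 px².

## The synthetic-colony generator

The generator emulates the features the analysis must cope with, with
exported ground truth (per-nucleus positions and radii, cluster structure,
per-MHC-region true counts, true D_f / U_i):

* nuclei are flat-intensity disks (default intensity 0.8, radius
  ~N(6, 0.5²) px, clipped) with a soft 1-px linear edge; centers snap to
  integer pixels so equal-radius nuclei rasterize identically;
* overlap clusters (doublets, multiplets of 3–4) chain their members
  1.35–1.6 mean radii apart with turns bounded to ±30°, so overlaps stay
  pairwise and the union-of-disks merged area is below the sum of parts, as
  in real clumps; `cluster_spacing=(1.7, 1.9)` approximates overlap-clean
  doublets whose merged area is ≈ 2 single areas;
* isolated nuclei are separated by more than two maximal radii; clusters
  never touch each other;
* MHC+ cytoplasm is rendered as irregular filled polygons (default two,
  radius ~70 px on a 384×384 field, intensity 0.7); whole clusters are
  placed inside polygons until the requested in-MHC nucleus fraction
  (default 0.5) is reached, with ≥ 4 px of clearance so centroids stay
  inside after segmentation — the achieved fraction is recorded in the
  truth table;
* additive Gaussian noise (default sd 0.02) on all channels and a few 1–3
  px bright debris specks exercise the opening and `min_area` decisions;
* intensities are quantized to the 8-bit grid, so PNG round-trips are
  lossless; everything derives from one seeded generator, so a seed fixes
  the image and truth bit for bit. Infeasible packings raise a generation
  error after bounded retries.

What the generator does **not** emulate: point-spread blur, uneven
illumination, chromatic bleed-through, texture within nuclei, myotube
morphology (MHC regions are convex-ish blobs, not elongated tubes), or
staining-intensity variation between cells. Passing tests therefore
demonstrate the correctness of the algorithmic chain and its behavior
under controlled overlap and noise, not performance on real micrographs —
on real data the per-channel *R*, *T* and the peak bounds must be tuned to
the staining quality.

## Test and script problem sizes

The automated checks run the pipeline on 384×384 synthetic colonies of
~25–40 nuclei: 10-image batches for recovery checks, 200 randomized
colonies for the metric identities, all 2¹⁶ exhaustive 4×4 masks plus 100
random 64×64 masks for the labeling oracle, and 1,000 replicates of n = 20
for the null calibration of the group comparison. The acceptance script
reuses these sizes with all randomness derived from its `--seed`.

## Known limitations

* The area-ratio quantity is biased low for heavily overlapping clumps
  (merged area < k × single area); this is inherent to size-based counting
  and is why heavily clumped colonies benefit from user-tuned peak bounds.
* Large singles and tight small doublets genuinely overlap in area; no
  size-only rule can separate them. Shape-based discrimination would be a
  natural extension.
* One MHC+ blob containing several touching myotubes is counted as one
  region.
* Cloning efficiency needs plate-layout metadata the images lack and is
  out of scope.
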