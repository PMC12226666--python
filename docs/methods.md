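# Methods

This note documents the models, conventions and numerical choices
behind `ribfuse`: what each stage computes, which parameters matter,
what the synthetic phantoms do and do not emulate, and where the design
was genuinely open.

## Coordinate and label conventions

All geometry lives in 0-based voxel indices; boxes are half-open
(`[min_corner, max_corner)`), so a 10×10×10 box covers exactly 1,000
voxels. Physical quantities (sphere radii, jitter, separations) are in
millimetres and converted through the per-axis voxel spacing, so
anisotropic grids are handled throughout. Rib labels are 1–12 for left
ribs 1–12 (cranial→caudal) and 13–24 for the right side; readers with
other encodings should remap before loading. CWIS labels are
lower-case; readers normalize case on input.

## Ensemble fusion

Each of the three category detectors (type, displacement, location)
emits scored boxes with one label. Fusion proceeds in three steps:

1. **Within-model NMS.** Boxes are visited by descending score (ties
   broken lexicographically by corner, for determinism); a box is kept
   iff its IoU with every kept box is ≤ `dedup_iou_threshold` (default
   0.5, i.e. suppress when overlap *exceeds* 50%). Greedy suppression
   is idempotent and order-independent given the tie-break.
2. **Cross-model grouping.** An overlap graph connects boxes of
   *different* models; the default edge criterion is any positive
   intersection volume (an IoU-threshold mode is available). Groups are
   connected components — deterministic and order-independent even when
   overlap is non-transitive. Components touching only one model are
   discarded: a finding needs at least two models' support.
3. **Merging.** Per model present, the highest-scoring box in the
   component represents it (consistent with the within-model rule);
   the fused box is the smallest axis-aligned box containing all
   representatives; a category whose model is absent gets the label
   `"unknown"` (at most one, by the ≥2-of-3 rule); the fused score is
   the mean of representative scores (max is selectable). Each fused
   detection keeps its per-category source scores and contributor set
   for auditability.

Open point resolved here: whether the detection score threshold (the
operating point) applies before or after fusion is not fixed by the
protocol; `ribfuse` applies it **after** fusion by default
(`apply_score_threshold` on fused detections), since the fused score is
what the operating point is calibrated on. Thresholding raw boxes
first is possible by filtering the inputs.

## Rib assignment

Detections are compared against a numbered rib segmentation by voxel
overlap inside the (grid-clipped) box; the rib with the maximum overlap
count wins. Any positive overlap suffices — a box overlapping no rib
voxel is discarded. Ties (rare; only on degenerate segmentations) go to
the lower anatomical rib number, then left before right, keeping
assignment deterministic and order-invariant.

The label-map validator automates the structural quality criteria used
for rib numberings: per label it reports voxel and connected-component
counts (26-connectivity), and flags missing labels per side, labels
with more than two fragments (two fragments are tolerated — a displaced
fracture legitimately splits a rib whose fragments should share one
label), and stray labels. A cage with exactly 11 pairs bilaterally is
flagged informationally as a "short cage" anatomical variant rather
than as missing-label errors; no renumbering is attempted for such
cases.

## Matching and detection metrics

References encode fractures as spheres (default radius 10 mm) centered
on the fracture. A detection may match a reference iff its box
intersects the sphere; the test clamps the sphere center into the box
and compares the clamped offset against per-axis voxel radii, which
makes the criterion exact under anisotropic spacing.

Matching is one-to-one per scan and maximizes the number of true
positives (Hungarian assignment on a feasibility-dominated reward);
among maximum matchings, higher-scoring detections are preferred as the
matched ones, with center distance as the final tie-break. A pure
greedy-by-score scan can strand a reference that only a lower-scored
detection could serve, undercounting TPs, which is why the optimal
matching is used; the observable conventions are unchanged — a fracture
detected twice yields one TP (the higher score) and one FP. Unmatched
detections are FPs, unmatched references FNs; count conservation
(TP+FN = references, TP+FP = detections) is asserted on every run.

Metrics are pooled over scans (not per-scan averaged; a per-scan macro
sensitivity is exposed separately): sensitivity TP/(TP+FN), precision
TP/(TP+FP), F1 their harmonic mean, FPPS ΣFP/n_scans. Rounding happens
only at presentation: whole percent for rates, two decimals for FPPS.
Per-class sensitivity/precision and the composition of missed fractures
are computed per category value, with empty classes reported absent
(NaN). Confusion matrices count reference→predicted label pairs over
TPs only — a missed fracture cannot be classified — with an `unknown`
column. Rib-number accuracy is the share of TPs whose assigned rib
equals the reference rib, over TPs where both are known (false
positives have no true rib, so they are excluded from the denominator).

The operating point for a target sensitivity (e.g. 82% on a training
set) is the largest score threshold whose pooled sensitivity still
meets the target; sensitivity is non-increasing in the threshold, so a
descending sweep over the distinct scores finds it exactly. An
unattainable target returns min-score − ε with a warning.

Slice-spacing (or any other) stratification reuses the pooled metrics
within scan groups; no significance testing between strata is provided,
only the descriptive per-group numbers.

## Interobserver agreement

Two observers' annotations are paired per scan by sphere intersection
(center distance ≤ sum of the two 10 mm radii), greedy by ascending
distance, one-to-one. The overlap summary (mutual / only-1 / only-2 /
union) and the paired-label table feed the statistics:

- **Cohen's κ** = (p_o − p_e)/(1 − p_e) on complete pairs, p_e from
  marginal products. Both raters constant and identical (p_e = 1) is
  reported as perfect agreement.
- **Krippendorff's α** = 1 − D_o/D_e with the nominal metric over the
  coincidence matrix; units with a single rating contribute nothing, so
  one-sided annotations are handled natively. For two raters and
  complete data α and κ agree to O(1/n).
- **95% CIs** by percentile bootstrap over fractures (units), n_boot =
  1,000, seeded; undefined resamples are redrawn (capped at 10×n_boot).
  The bootstrap unit is the fracture, not the scan — fracture-level
  resampling matches the statistic's unit of analysis.
- **Interpretation bands** (default scale): ≤ 0 Poor, then Slight,
  Fair, Moderate in 0.2 steps, (0.60, 0.80] Substantial, (0.80, 0.90]
  Strong, (0.90, 1] Almost perfect. Reader studies in this area band
  0.74 as "Substantial" and 0.82 as "Strong", which this scale
  reproduces; the classical Landis–Koch labels are selectable.
- **Disagreement decomposition**: per-category disagreement counts on
  mutual fractures, their sum as "classification tasks", and the number
  of distinct fractures with ≥ 1 disagreement.

## Phantom simulator

The phantom emulates exactly what downstream code consumes — a
numbered rib label map plus ground-truth fracture records — not CT
intensities, soft tissue, or scanner artifacts. Ribs are 4 mm-radius
tubes along elliptical arcs (12 or 11 pairs) stacked on a thoracic
ellipsoid in a 128³ grid at 2 mm isotropic spacing (fast to generate
and large enough for ~24 well-separated ribs; configurable upward).
Fracture centers are sampled on rib centerlines — so every center voxel
carries its rib's label — with a 30 mm minimum separation so reference
spheres stay unambiguous. Location is the arc-length third from the
spine (posterior / lateral / anterior), an explicit simulation
convention standing in for the clinical measurement-based rule, which
is not public. Type and displacement are drawn from configurable
frequency tables; the defaults (simple .70/wedge .20/complex .10;
undisplaced .55/offset .25/displaced .20; anterior .20/lateral
.40/posterior .40) encode the qualitative shape of blunt-trauma series
— simple undisplaced fractures dominate, complex are rare — because no
public per-class table was available to copy. The default 9 fractures
per scan reflects the prevalence in a validation set of ~300 fractures
over 34 scans. `split_displaced` optionally carves the rib of a
displaced fracture into two same-label fragments (as real displaced
fractures appear in segmentations); it is off by default because the
carved gap removes the rib label under the fracture center, which the
center-on-rib construction guarantee otherwise provides.

The detector simulator draws, per fracture, one shared uniform variate
used by all three category heads (a head detects iff the variate is
below its sensitivity), and one shared set of false-finding locations
(Poisson count, placed on rib voxels, a configurable fraction off-rib);
jitter, box sizes, label confusion and Beta-distributed scores come
from per-category streams. Sharing the detection events reflects that
the three heads look at the same image — with independent events the
≥2-model consensus would implicitly re-scale the ensemble sensitivity,
and isolated false findings would never survive fusion, making the
profile's parameters meaningless at the pipeline level. False findings
are also kept ≥ 40 mm from true fractures and from each other
(`fp_min_sep_mm`): "mean FP per scan" then denotes *distinct* false
findings at the fused level rather than a rate partially absorbed into
neighbouring detections. TP scores default to Beta(6, 2) and FP scores
to Beta(2, 4), overlapping enough that operating-point selection is a
real trade-off.

What passing phantom tests does **not** show: robustness to real
segmentation errors (mislabeled or merged ribs), scanner artifacts,
anatomically realistic rib curvature, or detector failure modes
correlated with fracture subtlety — the simulator's misses are random,
real misses concentrate on undisplaced hairline fractures.

## Problem sizes and determinism

Every stochastic component takes an explicit seed (numpy
`default_rng`/`SeedSequence`); same seed, same bits. The test suite
runs the oracle comparisons on 1,000 suppression instances and 300
matching instances, fusion fuzzing on 500 instances, and the
parameter-recovery study on 100 phantom scans (~900 fractures), which
gives 3-standard-error bands of about ±4 percentage points on
sensitivity and ±0.32 on FPPS; the reproduction script uses the same
100-scan study.
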