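# Methods

This note documents the models, conventions and numerical choices behind
`her2seg`, and what the synthetic fixtures do and do not demonstrate.

## Label schema

Six classes with fixed integer codes: background 0, the four invasive
HER2 expression grades 0/1+/2+/3+ as codes 1–4, non-invasive (in situ)
tumor as code 5. The four invasive classes carry ordinal grades 0–3;
each class belongs to one supercategory (background / invasive /
non-invasive). Codes are an on-disk contract: masks serialize as plain
8-bit rasters. Rasters are 0-based (row, col) with origin top-left and
half-open extents. Argmax over probability maps breaks ties toward the
lowest class id, so conversion is deterministic.

## Polygon rasterization

Annotations are GeoJSON polygons in pixel coordinates at the mask's
stated spacing (a `--scale` flag converts between resolutions, e.g.
0.5 → 2.0 µm/px). A pixel belongs to a polygon when its center
(col + 0.5, row + 0.5) lies inside the cleaned geometry (invalid
self-intersecting rings are repaired and the largest polygonal part
kept). Polygons are painted in decreasing-area order with ties broken by
annotation id, so granular annotations — down to single cells — override
the coarse regions that contain them. The area-order rule is a
repository convention; equal-area overlap resolution is otherwise
arbitrary, and making it explicit keeps rasterization independent of
input ordering.

## Wasserstein Dice loss

The ground metric `m` is a symmetric 6×6 cost matrix with zero diagonal:
0.25 / 0.50 / 1.00 for one-, two- and three-grade confusions among the
invasive classes, 0.50 between invasive and non-invasive tumor, and 1.00
between background and everything else. With one-hot ground truth the
per-pixel Wasserstein distance between prediction `p̂(x)` and true class
`g(x)` reduces to the transport cost `W(x) = Σ_l m[g(x), l] p̂_l(x)`.
The loss aggregates these as

    E  = Σ_x W(x)
    TP = Σ_{x : g(x) ≠ bg} max(0, m[g(x), bg] − W(x))
    loss = 1 − 2·TP / (2·TP + E)

This aggregation is normative for the package: several aggregation
variants circulate for generalized Wasserstein Dice losses, and fixing
the formula (rather than deferring to any one external implementation)
makes all numerical contracts testable. Per-term clamping at zero guards
arbitrary metrics; for the metric above it is provably inactive because
every cost to background is maximal. An all-background truth degenerates
to `E / (E + ε)` with ε = 1e-5, so training batches without foreground
still produce a finite, informative value. The combined training
objective adds mean per-pixel cross-entropy with 1:1 weights — the
weighting of the conventional CE + Dice combination the loss slots into;
both weights are configurable. An analytic gradient with respect to the
probability raster is provided and verified against central differences.

## Sliding-window inference

Defaults: 512×512 patches at the 2.0 µm/px working resolution, 50 %
overlap (stride 256), Gaussian fusion window with σ = patch/8 floored at
1e-8, peak normalized to 1. σ and overlap are inherited conventions from
the patch-inference tooling this engine mirrors and are configurable.
Padding is half-sample symmetric reflection: it preserves the bright
histology background (zero padding would create dark borders) and, unlike
whole-sample reflection, stays defined when the required pad meets or
exceeds the image size (images smaller than one patch).

Foreground detection skips near-white patches: a patch is segmented only
if the 5th percentile of its per-pixel minimum channel intensity falls
below 250 (8-bit). The minimum channel is a convention chosen for
robustness to single-stain tissue (brown-only or blue-only material stays
dark in at least one channel). Skipped patches contribute an explicit
one-hot background distribution under the same window weights rather
than zero weight, so even a fully white slide yields a defined,
normalized probability map. Fused probabilities are renormalized
per pixel; for a constant segmenter the fused map is exactly constant
(no seam artifacts), and for any per-pixel segmenter fusion reproduces
direct full-image evaluation to machine precision.

Resampling between scanner resolution and the working resolution uses
area averaging (antialiased), appropriate for stain intensity.

## Post-processing

Tissue components are connected components (8-connectivity by default;
blob-like regions, configurable) of the union of all five non-background
classes — invasive and non-invasive pixels co-occur in one physical
region, and the boundary of a non-invasive lesion is usually segmented
correctly from local context even when its interior is not. A component
whose non-invasive fraction is at least one-third (inclusive) is
relabelled entirely as non-invasive. The operation is idempotent,
monotone in non-invasive content, and never touches background. No
minimum component size is applied by default.

## Multi-annotator consensus

Class-level majority voting can misrepresent tissue (three raters
splitting across three grades can be outvoted by two non-invasive
votes), so consensus is hierarchical: per pixel, plurality vote over the
three supercategories, then — if invasive wins — the median HER2 grade
over exactly the raters who voted invasive. Two conventions close gaps
the two-stage description leaves open, both configurable in principle
and fixed here for determinism:

- Supercategory ties break with priority invasive > non-invasive >
  background: missing invasive tumor is the clinically costlier error.
- Half-grade medians (even voter counts) round up, mirroring the
  observed tendency to push borderline cases toward 2+ so follow-up
  testing happens.

Pairwise agreement matrices report mean F1 between every pair of raters
over the five tissue classes; classes absent from both masks of a pair
are excluded from that pair's mean.

## Evaluation metrics

- **Mean F1**: average of per-class F1 over the four grades plus
  non-invasive; background excluded. Classes absent from both masks are
  dropped rather than scored perfect, so small regions of interest do not
  inflate the mean.
- **Weighted κ**: linearly weighted Cohen's kappa (weights
  `1 − |i−j|/3`) over the grades, restricted to pixels where *both*
  masks are invasive. The restriction is a convention: it makes the
  statistic a pure grade-agreement measure, untouched by background or
  non-invasive relabelling (consistent with the observation that
  non-invasive post-processing leaves κ essentially unchanged).
  κ is explicitly undefined (raises) when no pixel is jointly invasive.
- **Concordance F1**: per pixel, an oracle reference adopts the
  prediction wherever it matches at least one annotator and falls back
  to the consensus otherwise; mean F1 against this oracle. By
  construction it never falls below mean F1 against the consensus.
- **Case-level score metrics**: accuracy, mean F1 over the four score
  classes, linear-weighted κ on the 0–3 scale; status-level accounting
  maps scores to negative / HER2-low / equivocal / positive (FISH
  resolving equivocal cases), and reports referral counts, HER2-low
  accuracy (a true-low case counts as handled when called 1+ directly or
  routed through an equivocal prediction), and false-negative positives.

## Scoring rules

With `r_k` the fraction of invasive pixels at grade ≥ k (non-invasive
and background excluded): 3+ if `r3 > t3`, 2+ if `r2 > t2` and
`r1 > t1`, 1+ if `r1 > t1`, else 0. All thresholds default to 10 % with
strict inequalities — a ratio of exactly 10 % falls to the lower score.
The 2+ rule is gated by the 1+ rule. At the default thresholds the gate
is vacuous (`r2 > t2` implies `r1 ≥ r2 > t1`); it matters only for the
calibrated variant, where `t2` drops to 5 % to mimic pathologists'
conservative handling of borderline 1+/2+ slides. The gate confines the
calibration to exactly those slides: lowering `t2` can then only promote
a 1+ to a 2+, never lift a slide that fails every 10 % rule, which is
the intended clinical semantics of the calibration.

The safety margin `m` implements an uncertainty band: a slide is
excluded when any ratio lies in `(t − m, t + m]`. The symmetric band is
the default because uncertainty is two-sided — a HER2 0 call with
`r1 = 9.9 %` is as fragile as a 1+ call at 10.1 % — and a one-sided
variant (excluding only `(t, t + m]`) is available by flag. The margin
must be smaller than every threshold. Inclusion is antitone in `m`.

Region reports recompute the distribution, ratios and score per
rectangle or polygon, enabling the spatial interpretability use case
(heterogeneous slides dissected into regions with their own HER2
distributions); regions without invasive pixels report their
distribution with an undefined score.

## Synthetic fixtures

The generators define the package's study conditions.

- **Label masks**: tissue is the upper level set of Gaussian-smoothed
  noise (σ = extent/16, tissue fraction 0.45 of the canvas); grades are
  assigned along level sets of a second smooth field by exact pixel
  counts, so realized cumulative ratios match targets to within one
  pixel of rounding and grade regions are spatially coherent bands. An
  optional non-invasive region (12 % of tissue) is carved the same way,
  with its share of every connected component capped at 25 % so
  post-processing is provably a no-op on ground truth.
- **Pseudo-IHC renders**: near-white background (all channels ≥ 252),
  grade-dependent brown shades whose blue channel encodes staining
  density in four separated bands, a sparse (3 %) darker nuclear speckle
  kept inside its grade's band, ±4 intensity noise, and a blue-violet
  hue marker for non-invasive tissue. The palette is co-designed with
  the rule-based demo segmenter so the render → segment round trip is
  exact on tissue; this makes end-to-end pipeline tests deterministic.
- **Annotator noise**: perturbation operates on regions (connected
  components of constant class), not pixels, because the emulated
  protocol has raters relabelling shared polygons. Grade shifts draw a
  uniform ± direction and clamp into 0–3; with 30 % adjacent-grade
  confusion and five raters, majority-vote arithmetic predicts ≈97 %
  per-region recovery for boundary grades (error requires three of five
  raters shifting in the one registering direction, ≈2.7 %) and ≈95 %
  for interior grades (two shift directions available).
- **Cohorts**: stratified by target score via largest-remainder
  allocation. Per-score ratio windows keep clean cases clear of the 10 %
  thresholds and outside a 5 % uncertainty band (e.g. 2+ cases draw
  `r2 ∈ [0.20, 0.45]`, `r3 ≤ 0.04`); a separate borderline generator
  places `r2` within ±2 % of the 2+ threshold to exercise calibration
  and margin logic. Every stored true score is recomputed from the
  case's own mask. Default problem sizes (256² masks for fixtures, 192²
  for cohort runs, 40-case cohorts, 50-seed consensus experiments) keep
  the full verification suite at desk scale.

What passing these fixtures shows: the deterministic contracts —
scoring, calibration, margins, consensus, post-processing, fusion — are
correct, and the whole pipeline composes without loss of information.
What it does not show: segmentation accuracy on real stained tissue.
Real IHC has continuous, heterogeneous staining, membrane-level texture,
focal artifacts and genuinely ambiguous 1+/2+ intensities; the renders
are flat-shaded stand-ins, and the demo segmenter is a color rule, not a
trained model. Claims about clinical performance require a trained
backend and clinical slides, which this package deliberately treats as
pluggable inputs.

## Numerical choices and degenerate inputs

- Loss smoothing ε = 1e-5 (empty-foreground batches).
- Probability maps validated to per-pixel sum 1 within 1e-6; fused maps
  renormalized after weighted averaging; float32 storage error
  renormalized on read.
- Gaussian window floored at 1e-8 so every covered pixel has positive
  weight; peak exactly 1 for even and odd patch sizes.
- Cross-entropy clips probabilities at 1e-12.
- κ returns 1 when degenerate marginals force expected agreement to 1.
- Scoring raises a dedicated no-invasive-tissue error (CLI exit code 3),
  mirroring the exclusion of slides without invasive tumor from cohorts.
- All generators take explicit integer seeds; identical seeds give
  byte-identical masks, renders and cohorts.

## Known limitations

- The ground metric's aggregation is fixed by this package; other
  Wasserstein-Dice aggregation variants will give different loss values
  (not different orderings for the metrics used here).
- The hierarchical consensus tie-break and median rounding are
  conventions; alternative choices shift borderline pixels between 1+/2+
  and between supercategories.
- Pixel proportions stand in for cell proportions throughout scoring;
  no cell-level counting or membrane-completeness analysis is performed.
- The weighted κ convention excludes non-invasive tissue from the
  ordinal scale; treating it as a fifth level would change values.
- WSI reading is limited to single-region extraction; pyramid
  management belongs to the caller.
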