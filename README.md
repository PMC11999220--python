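# her2seg

Interpretable whole-slide HER2 scoring from six-class tissue segmentation
masks.

HER2 (human epidermal growth factor receptor 2) status drives therapy
selection in breast cancer. Pathologists determine it from
immunohistochemically stained sections by grading the membrane staining of
invasive tumor cells as 0, 1+, 2+ or 3+ and applying the ASCO/CAP
guidelines, with non-invasive (in situ) carcinoma excluded from scoring.
The process is slow and shows substantial inter-rater variability.

`her2seg` implements a fully automatic, pixel-level alternative. Any
segmentation backend that emits per-pixel probabilities over six tissue
classes — the four invasive HER2 grades, non-invasive tumor, and
background — plugs into a pipeline that produces a guideline-based,
auditable slide score, together with the machinery needed to train and
evaluate such a backend:

- **Label schema and rasters** (`core`): six-class masks, probability
  maps, class distributions, mask/probability-map IO.
- **Annotation handling** (`annotation_io`): GeoJSON polygon annotations
  rasterized with area-ordered painting so granular polygons override
  coarse regions.
- **Wasserstein Dice loss** (`wdice`): a training loss over an ordinal
  ground metric. With one-hot truth, the per-pixel transport cost is
  `W(x) = Σ_l m[g(x), l] p̂_l(x)` with penalties `m` of 0.25 / 0.50 /
  1.00 for one-, two- and three-grade confusions, 0.50 for mixing
  invasive and non-invasive tumor, 1.00 against background; the loss is
  `1 − 2TP / (2TP + Σ_x W(x))` with
  `TP = Σ_{g(x)≠bg} max(0, m[g(x), bg] − W(x))`.
- **Sliding-window inference** (`inference`): 512-px patches at
  2.0 µm/px, 50 % overlap, Gaussian-weighted fusion (σ = patch/8),
  reflection padding, and skipping of near-white patches (5th-percentile
  intensity ≥ 250).
- **Post-processing** (`postprocess`): connected tissue components with at
  least one-third non-invasive pixels are promoted entirely to
  non-invasive.
- **Consensus and agreement** (`consensus`, `metrics`): hierarchical
  multi-annotator fusion (supercategory vote, then median HER2 grade),
  mean F1 over the five tissue classes, linearly weighted Cohen's κ on
  the grades, and Concordance F1 (a prediction counts as correct if any
  annotator agrees).
- **Scoring** (`scoring`): with `r_k` the fraction of invasive pixels at
  grade ≥ k, the cascade is 3+ if `r3 > 10 %`, 2+ if `r2 > t2` (default
  10 %, calibrated 5 %), 1+ if `r1 > 10 %`, else 0; strict inequalities.
  A safety margin `m` excludes slides whose ratios land within
  `(t − m, t + m]` of any threshold as uncertain. Scores map to clinical
  status (0 negative, 1+ HER2-low, 2+ equivocal → FISH, 3+ positive).
- **Synthetic fixtures** (`synthetic`): label masks with prescribed grade
  composition, pseudo-IHC renders, region-wise annotator noise, and
  stratified cohorts with recomputable true scores.

## Worked example

Generate a synthetic case, render it, and score it end to end with the
built-in rule-based demo segmenter:

```python
from her2seg.synthetic import generate_label_mask, render_pseudo_ihc
from her2seg.pipeline import run_pipeline

mask, dist = generate_label_mask(256, 256, target_ratios=(0.55, 0.30, 0.18), seed=7)
image = render_pseudo_ihc(mask, seed=7)
result = run_pipeline(image=image)
print(result.to_json())
```

```json
{
  "config_hash": "e87d1c8d22526227",
  "distribution": {
    "0": 36045, "1": 11679, "2": 6488, "3": 3114, "4": 4671, "5": 3539
  },
  "n_invasive": 25952,
  "ratios": {
    "r1": 0.5499768803945746,
    "r2": 0.2999768803945746,
    "r3": 0.17998612823674476
  },
  "region": null,
  "score": 3,
  "status": "positive"
}
```

Of the 25 952 invasive tumor pixels, 55.0 % carry grade ≥ 1+, 30.0 %
grade ≥ 2+ and 18.0 % grade 3+. Since `r3 = 0.18 > 0.10`, the slide is
scored HER2 3+, i.e. HER2 positive — matching the composition the
generator was asked for. The 3 539 non-invasive pixels (class 5) are
excluded from every ratio.

The same stages are available from the shell:

```sh
her2 simulate cohort --n 8 --seed 4 --out cohort/
her2 score --mask cohort/case_000_mask.png --calibrated --margin 0.05
her2 run --image tile.png --backend heuristic --out outdir/
```

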