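"""Synthetic pseudo-IHC fixtures with known ground truth.

The generators emulate the geometry and statistics the pipeline is built
for — blob-shaped tumor regions with a prescribed HER2 grade composition,
near-white-background renders with brown membrane staining in four
intensity bands, region-structured annotator label noise, and stratified
cohorts whose true scores are recomputable from their masks — without
attempting photorealistic histology.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.measure import label as cc_label

from .consensus import MaskStack
from .core import (
    BACKGROUND,
    ClassDistribution,
    INVASIVE_CLASSES,
    LabelMask,
    NONINVASIVE,
    SchemaError,
    class_distribution,
    class_for_grade,
)
from .scoring import ScoringRules, her2_ratios, her2_score

__all__ = [
    "CohortSpec",
    "AnnotatorNoiseModel",
    "SyntheticCase",
    "generate_label_mask",
    "render_pseudo_ihc",
    "simulate_annotators",
    "generate_cohort",
    "generate_borderline_cases",
    "GRADE_COLORS",
    "NONINVASIVE_COLOR",
]

# Render palette, co-designed with her2seg.inference.heuristic_segment:
# brown (R > B) with the blue channel encoding staining density in four
# separated bands; non-invasive carries a blue-over-red hue marker.
GRADE_COLORS = {
    0: (210, 190, 175),  # faint / no staining
    1: (190, 155, 125),  # incomplete faint staining
    2: (160, 115, 80),  # weak-moderate complete staining
    3: (120, 70, 35),  # intense circumferential staining
}
NONINVASIVE_COLOR = (150, 130, 190)
_SPECKLE_FACTOR = 0.9  # nuclear speckle: darker shade within the same band
_SPECKLE_RATE = 0.03
_COLOR_NOISE = 4


@dataclass
class CohortSpec:
    """Recipe for a stratified synthetic cohort."""

    n_cases: int = 40
    score_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    composition_jitter: float = 0.05
    noninvasive_prob: float = 0.5
    seed: int = 0
    mask_shape: tuple[int, int] = (256, 256)

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise SchemaError("n_cases must be positive")
        if abs(sum(self.score_mix) - 1.0) > 1e-9:
            raise SchemaError("score_mix must sum to 1")


@dataclass
class AnnotatorNoiseModel:
    """Region-wise label perturbation probabilities.

    Noise operates on regions, not pixels: annotators in the emulated
    protocol relabel shared polygons, so disagreement is region-structured.
    Grade shifts draw a uniform +/- direction and clamp into 0..3.
    """

    adjacent_confusion: float = 0.0
    two_off_confusion: float = 0.0
    invasive_noninvasive_swap: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (self.adjacent_confusion, self.two_off_confusion, self.invasive_noninvasive_swap)
        if any(not 0 <= p <= 1 for p in probs):
            raise SchemaError("confusion probabilities must lie in [0, 1]")
        if sum(probs) > 1:
            raise SchemaError("confusion probabilities must sum to at most 1")


@dataclass
class SyntheticCase:
    case_id: int
    mask: LabelMask
    score: int
    ratios: tuple[float, float, float]
    borderline: bool = False


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator, sigma: float) -> np.ndarray:
    return gaussian_filter(rng.standard_normal(shape), sigma=sigma)


def _largest_remainder(total: int, fractions: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``fractions``."""
    raw = fractions * total
    base = np.floor(raw).astype(np.int64)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


def generate_label_mask(
    h: int,
    w: int,
    target_ratios: tuple[float, float, float],
    include_noninvasive: bool = True,
    seed: int = 0,
    tissue_fraction: float = 0.45,
    noninvasive_fraction: float = 0.12,
    spacing_um: float = 2.0,
) -> tuple[LabelMask, ClassDistribution]:
    """Blob-shaped label mask realizing prescribed cumulative HER2 ratios.

    ``target_ratios`` are the cumulative invasive fractions (r1, r2, r3).
    Tissue is the upper level set of a smoothed noise field; grades are
    assigned along the level sets of a second field, so each grade forms
    spatially coherent bands and the realized ratios match the targets to
    within a pixel of rounding (far inside the +/-1% contract).
    """
    r1, r2, r3 = target_ratios
    if not (0 <= r3 <= r2 <= r1 <= 1):
        raise SchemaError(f"need 0 <= r3 <= r2 <= r1 <= 1, got {target_ratios}")
    rng = np.random.default_rng(seed)
    sigma = max(h, w) / 16.0

    field = _smooth_field((h, w), rng, sigma)
    thresh = np.quantile(field, 1.0 - tissue_fraction)
    tissue = field > thresh
    if not tissue.any():
        raise SchemaError("degenerate tissue field; increase the canvas")

    out = np.zeros((h, w), dtype=np.uint8)
    tissue_idx = np.flatnonzero(tissue.ravel())

    if include_noninvasive and noninvasive_fraction > 0:
        ni_field_full = _smooth_field((h, w), rng, sigma).ravel()
        ni_field = ni_field_full[tissue_idx]
        n_ni = max(1, int(round(noninvasive_fraction * tissue_idx.size)))
        ni_sel = tissue_idx[np.argsort(-ni_field)[:n_ni]]
        # Cap the non-invasive share of every tissue component at 25% so the
        # one-third post-processing promotion is provably a no-op on truth.
        comps = cc_label(tissue, connectivity=2).ravel()
        ni_mask = np.zeros(h * w, dtype=bool)
        ni_mask[ni_sel] = True
        kept: list[np.ndarray] = []
        for cid in range(1, comps.max() + 1):
            comp_idx = np.flatnonzero(comps == cid)
            comp_ni = comp_idx[ni_mask[comp_idx]]
            cap = int(0.25 * comp_idx.size)
            if comp_ni.size > cap:
                keep = comp_ni[np.argsort(-ni_field_full[comp_ni], kind="stable")[:cap]]
            else:
                keep = comp_ni
            kept.append(keep)
        ni_sel = np.concatenate(kept) if kept else np.array([], dtype=np.int64)
        out.ravel()[ni_sel] = NONINVASIVE
        inv_idx = np.setdiff1d(tissue_idx, ni_sel, assume_unique=True)
    else:
        inv_idx = tissue_idx

    # per-grade fractions from the cumulative targets
    fractions = np.array([1.0 - r1, r1 - r2, r2 - r3, r3])
    counts = _largest_remainder(inv_idx.size, fractions)
    grade_field = _smooth_field((h, w), rng, sigma).ravel()[inv_idx]
    order = inv_idx[np.argsort(grade_field, kind="stable")]
    start = 0
    for grade, n in enumerate(counts):
        out.ravel()[order[start : start + n]] = class_for_grade(grade)
        start += n

    mask = LabelMask(out, spacing_um=spacing_um)
    return mask, class_distribution(mask)


def render_pseudo_ihc(mask: LabelMask, seed: int = 0) -> np.ndarray:
    """Render a label mask as a pseudo-IHC RGB image (uint8).

    Background is near-white (every channel >= 252); invasive regions get
    their grade's brown shade plus a sparse darker nuclear speckle whose
    color stays inside the grade's density band; non-invasive regions use
    the blue-violet hue marker.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    h, w = mask.shape
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = rng.integers(252, 256, size=(h, w, 3))

    for grade, color in GRADE_COLORS.items():
        sel = mask.data == class_for_grade(grade)
        img[sel] = color
    img[mask.data == NONINVASIVE] = NONINVASIVE_COLOR

    tissue = mask.data != BACKGROUND
    speckle = tissue & (rng.random((h, w)) < _SPECKLE_RATE)
    img[speckle] *= _SPECKLE_FACTOR
    noise = rng.integers(-_COLOR_NOISE, _COLOR_NOISE + 1, size=(h, w, 3))
    img[tissue] += noise[tissue]
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _class_regions(mask: LabelMask) -> np.ndarray:
    """Region id raster: connected components of constant non-background
    class (8-connectivity); background is region 0."""
    regions = np.zeros(mask.shape, dtype=np.int64)
    next_id = 1
    for cls in (*INVASIVE_CLASSES, NONINVASIVE):
        sel = mask.data == cls
        if not sel.any():
            continue
        lab = cc_label(sel, connectivity=2)
        regions[sel] = lab[sel] + next_id - 1
        next_id += lab.max()
    return regions


def simulate_annotators(
    truth: LabelMask, model: AnnotatorNoiseModel, k: int = 5
) -> MaskStack:
    """Simulate k annotators relabelling the truth's regions.

    All annotators share the truth's geometry (as in a protocol where one
    rater outlines polygons and the others adjust labels); each region's
    label is independently perturbed per annotator.  A zero-noise model
    returns k copies of the truth.
    """
    if k < 2:
        raise SchemaError("need at least two annotators")
    rng = np.random.default_rng(model.seed)
    regions = _class_regions(truth)
    n_regions = int(regions.max())
    region_class = np.zeros(n_regions + 1, dtype=np.int64)
    flat_r, flat_c = regions.ravel(), truth.data.ravel()
    region_class[flat_r] = flat_c  # constant per region by construction

    p_adj, p_two, p_swap = (
        model.adjacent_confusion,
        model.two_off_confusion,
        model.invasive_noninvasive_swap,
    )
    masks = []
    for _ in range(k):
        newcls = region_class.copy()
        u = rng.random(n_regions + 1)
        direction = rng.choice((-1, 1), size=n_regions + 1)
        rand_grade = rng.integers(0, 4, size=n_regions + 1)
        for rid in range(1, n_regions + 1):
            cls = region_class[rid]
            if cls == NONINVASIVE:
                if u[rid] < p_swap:
                    newcls[rid] = class_for_grade(int(rand_grade[rid]))
                continue
            grade = cls - 1
            if u[rid] < p_adj:
                newcls[rid] = class_for_grade(int(np.clip(grade + direction[rid], 0, 3)))
            elif u[rid] < p_adj + p_two:
                newcls[rid] = class_for_grade(int(np.clip(grade + 2 * direction[rid], 0, 3)))
            elif u[rid] < p_adj + p_two + p_swap:
                newcls[rid] = NONINVASIVE
        masks.append(
            LabelMask(newcls[regions].astype(np.uint8), truth.spacing_um, truth.origin)
        )
    return MaskStack(masks)


# ---------------------------------------------------------------------------
# cohorts

# Target-ratio windows per true score, chosen to keep clean cases clearly
# away from the 10% decision thresholds (and outside a 5% uncertainty band)
# while spanning a realistic range of compositions.
_SCORE_RECIPES = {
    0: dict(r1=(0.005, 0.045), r2=None, r3=None),
    1: dict(r1=(0.20, 0.60), r2=(0.0, 0.045), r3=(0.0, 0.03)),
    2: dict(r1=(0.25, 0.70), r2=(0.20, 0.45), r3=(0.0, 0.04)),
    3: dict(r1=(0.35, 0.90), r2=(0.25, 0.60), r3=(0.20, 0.45)),
}


def _draw_ratios(score: int, rng: np.random.Generator, jitter: float) -> tuple[float, float, float]:
    rec = _SCORE_RECIPES[score]

    def draw(window, lo_bound=0.0):
        lo, hi = window
        lo = max(lo, lo_bound)
        center = (lo + hi) / 2
        half = min((hi - lo) / 2, max(jitter, 1e-3) * 10)
        return float(rng.uniform(max(lo, center - half), min(hi, center + half)))

    if score == 0:
        r1 = draw(rec["r1"])
        r2 = rng.uniform(0, r1)
        r3 = rng.uniform(0, r2)
        return r1, float(r2), float(r3)
    r3 = draw(rec["r3"]) if rec["r3"] else 0.0
    r2 = max(draw(rec["r2"]), r3) if rec["r2"] else r3
    r1 = max(draw(rec["r1"]), r2)
    return r1, r2, r3


def generate_cohort(spec: CohortSpec) -> list[SyntheticCase]:
    """Stratified cohort of synthetic cases with recomputable true scores.

    Per-stratum counts follow the score mix by largest-remainder rounding
    (within one case of the targets); each case's stored score equals
    ``her2_score`` of its own mask under the default 10% rules.
    """
    rng = np.random.default_rng(spec.seed)
    counts = _largest_remainder(spec.n_cases, np.asarray(spec.score_mix, dtype=float))
    cases: list[SyntheticCase] = []
    cid = 0
    h, w = spec.mask_shape
    for score, n in enumerate(counts):
        for _ in range(int(n)):
            target = _draw_ratios(score, rng, spec.composition_jitter)
            mask, dist = generate_label_mask(
                h,
                w,
                target,
                include_noninvasive=bool(rng.random() < spec.noninvasive_prob),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            realized = her2_ratios(dist)
            true_score = her2_score(dist)
            if true_score != score:  # ratios drawn well clear of thresholds
                raise SchemaError(
                    f"case {cid}: realized score {true_score} != stratum {score}"
                )
            cases.append(SyntheticCase(cid, mask, true_score, realized))
            cid += 1
    return cases


def generate_borderline_cases(
    n: int,
    seed: int = 0,
    threshold: float = 0.10,
    spread: float = 0.02,
    mask_shape: tuple[int, int] = (256, 256),
) -> list[SyntheticCase]:
    """Cases whose r2 lands within ``spread`` of the 2+ threshold.

    These exercise the calibration and safety-margin logic: at a 5% margin
    every such case falls inside the exclusion band.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        r2 = float(rng.uniform(threshold - spread, threshold + spread))
        r1 = float(rng.uniform(0.30, 0.60))
        r3 = float(rng.uniform(0.0, 0.03))
        mask, dist = generate_label_mask(
            *mask_shape, (r1, max(r2, r3), r3), seed=int(rng.integers(0, 2**31 - 1))
        )
        out.append(
            SyntheticCase(i, mask, her2_score(dist), her2_ratios(dist), borderline=True)
        )
    return out
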