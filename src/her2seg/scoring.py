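"""Whole-slide HER2 scoring from class distributions.

The scoring rules mirror the ASCO/CAP guidelines under the assumption
that pixel proportions approximate cell proportions.  With r_k the
fraction of invasive tumor pixels at grade >= k,

    3+ : r3 > t3        (default t3 = 10%)
    2+ : r2 > t2        (default t2 = 10%; calibrated variant 5%)
    1+ : r1 > t1        (default t1 = 10%)
    0  : otherwise,

with strict inequalities, so a ratio landing exactly on a threshold falls
to the lower score.  Non-invasive and background pixels are excluded
entirely.  The 2+ threshold calibration to 5% mimics pathologists'
tendency to push borderline 1+/2+ cases toward 2+ so that follow-up
testing happens.

A safety margin m turns thresholds into exclusion bands: a slide whose
ratio lands within (t - m, t + m] of any threshold is reported EXCLUDED
(uncertain) rather than scored.  A one-sided variant excluding only
(t, t + m] is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .core import (
    BACKGROUND,
    ClassDistribution,
    LabelMask,
    NONINVASIVE,
    SchemaError,
    class_distribution,
    class_for_grade,
)

__all__ = [
    "EXCLUDED",
    "NoInvasiveTissueError",
    "ScoringRules",
    "MarginPolicy",
    "ScoreReport",
    "her2_ratios",
    "her2_score",
    "calibrated_rules",
    "calibrated_score",
    "score_with_margin",
    "score_to_status",
    "score_report",
    "region_report",
]

#: Sentinel score for slides excluded by the safety-margin policy.
EXCLUDED = "EXCLUDED"


class NoInvasiveTissueError(ValueError):
    """The mask contains no invasive tumor pixels, so no score exists."""


@dataclass(frozen=True)
class ScoringRules:
    """Ratio thresholds for the 3+/2+/1+ rules; comparisons are strict."""

    t3: float = 0.10
    t2: float = 0.10
    t1: float = 0.10

    def __post_init__(self) -> None:
        for name, t in (("t3", self.t3), ("t2", self.t2), ("t1", self.t1)):
            if not 0 < t <= 1:
                raise SchemaError(f"threshold {name} must lie in (0, 1], got {t}")


def calibrated_rules() -> ScoringRules:
    """Default rules with the 2+ threshold calibrated from 10% to 5%."""
    return ScoringRules(t3=0.10, t2=0.05, t1=0.10)


@dataclass(frozen=True)
class MarginPolicy:
    """Safety margin m around each threshold; ``rule`` picks band
    (symmetric, default) or one_sided ((t, t+m] only) exclusion."""

    margin: float = 0.0
    rule: Literal["band", "one_sided"] = "band"

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise SchemaError("margin must be non-negative")


def her2_ratios(dist: ClassDistribution) -> tuple[float, float, float]:
    """Cumulative invasive-pixel fractions (r1, r2, r3) at grades >= 1, 2, 3."""
    n_inv = dist.n_invasive
    if n_inv == 0:
        raise NoInvasiveTissueError("no invasive tumor pixels; slide cannot be scored")
    g = dist.grade_counts()
    r3 = g[3] / n_inv
    r2 = (g[2] + g[3]) / n_inv
    r1 = (g[1] + g[2] + g[3]) / n_inv
    return r1, r2, r3


def her2_score(dist: ClassDistribution, rules: ScoringRules | None = None) -> int:
    """Apply the threshold cascade to a class distribution.

    The 2+ rule is gated by the 1+ rule: a slide must already exceed the
    overall staining cutoff (r1 > t1) to be eligible for 2+.  With the
    default thresholds (all 10%) the gate is vacuous, since r2 > t2
    implies r1 >= r2 > t1; under the calibrated 5% 2+ threshold it
    confines the calibration's effect to the borderline 1+/2+ slides it
    is meant for, instead of promoting slides that fail every 10% rule.
    """
    rules = rules or ScoringRules()
    r1, r2, r3 = her2_ratios(dist)
    if r3 > rules.t3:
        return 3
    if r2 > rules.t2 and r1 > rules.t1:
        return 2
    if r1 > rules.t1:
        return 1
    return 0


def calibrated_score(dist: ClassDistribution) -> int:
    """Score with the 2+ threshold calibrated to 5%."""
    return her2_score(dist, calibrated_rules())


def score_with_margin(
    dist: ClassDistribution,
    rules: ScoringRules | None = None,
    policy: MarginPolicy | None = None,
) -> int | str:
    """Score a distribution, or return :data:`EXCLUDED` when any ratio
    falls inside a threshold's uncertainty band."""
    rules = rules or ScoringRules()
    policy = policy or MarginPolicy()
    m = policy.margin
    if m >= min(rules.t1, rules.t2, rules.t3):
        raise SchemaError("margin must be smaller than every threshold")
    r1, r2, r3 = her2_ratios(dist)
    if m > 0:
        for r, t in ((r1, rules.t1), (r2, rules.t2), (r3, rules.t3)):
            lo = t if policy.rule == "one_sided" else t - m
            if lo < r <= t + m:
                return EXCLUDED
    return her2_score(dist, rules)


def score_to_status(
    score: int, fish: bool | None = None
) -> Literal["negative", "low", "equivocal", "positive"]:
    """Map a HER2 score to clinical status.

    0 is negative, 1+ is HER2-low, 3+ is positive; 2+ is equivocal and is
    resolved by a FISH result when one is supplied (amplified -> positive,
    not amplified -> low).
    """
    if score == 0:
        return "negative"
    if score == 1:
        return "low"
    if score == 3:
        return "positive"
    if score == 2:
        if fish is None:
            return "equivocal"
        return "positive" if fish else "low"
    raise SchemaError(f"invalid HER2 score {score!r}")


@dataclass
class ScoreReport:
    """Slide- or region-level scoring result."""

    ratios: tuple[float, float, float] | None
    score: int | str | None
    n_invasive: int
    status: str | None = None
    distribution: dict[int, int] = field(default_factory=dict)
    region: str | None = None

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "ratios": None if self.ratios is None else {
                "r1": self.ratios[0], "r2": self.ratios[1], "r3": self.ratios[2]
            },
            "score": self.score,
            "status": self.status,
            "n_invasive": self.n_invasive,
            "distribution": {int(k): int(v) for k, v in self.distribution.items()},
        }


def score_report(
    dist: ClassDistribution,
    rules: ScoringRules | None = None,
    policy: MarginPolicy | None = None,
    fish: bool | None = None,
    region: str | None = None,
) -> ScoreReport:
    """Full report for one distribution: ratios, (possibly excluded)
    score, and status.  Regions without invasive tissue get an undefined
    score but still report their distribution."""
    if dist.n_invasive == 0:
        return ScoreReport(None, None, 0, None, dict(dist.counts), region)
    ratios = her2_ratios(dist)
    if policy is not None and policy.margin > 0:
        score: int | str = score_with_margin(dist, rules, policy)
    else:
        score = her2_score(dist, rules)
    status = score_to_status(score, fish) if isinstance(score, int) else None
    return ScoreReport(ratios, score, dist.n_invasive, status, dict(dist.counts), region)


def _region_distribution(mask: LabelMask, region) -> ClassDistribution:
    if isinstance(region, (tuple, list)) and len(region) == 4:
        r0, c0, h, w = (int(v) for v in region)
        if r0 < 0 or c0 < 0 or r0 + h > mask.shape[0] or c0 + w > mask.shape[1]:
            raise SchemaError(f"region {region} exceeds the mask extent")
        sub = mask.data[r0 : r0 + h, c0 : c0 + w]
        return class_distribution(LabelMask(sub, mask.spacing_um))
    # shapely polygon in (x, y) pixel coordinates
    from shapely import contains_xy

    minx, miny, maxx, maxy = region.bounds
    c0, c1 = max(0, int(minx)), min(mask.shape[1] - 1, int(np.ceil(maxx)))
    r0, r1 = max(0, int(miny)), min(mask.shape[0] - 1, int(np.ceil(maxy)))
    cols = np.arange(c0, c1 + 1) + 0.5
    rows = np.arange(r0, r1 + 1) + 0.5
    cc, rr = np.meshgrid(cols, rows)
    inside = contains_xy(region, cc.ravel(), rr.ravel()).reshape(cc.shape)
    values = mask.data[r0 : r1 + 1, c0 : c1 + 1][inside]
    counts = np.bincount(values, minlength=6)
    return ClassDistribution({c: int(n) for c, n in enumerate(counts) if n})


def region_report(
    mask: LabelMask,
    regions: Sequence | None = None,
    rules: ScoringRules | None = None,
    policy: MarginPolicy | None = None,
) -> list[ScoreReport]:
    """Score the whole mask plus any number of sub-regions.

    Regions are (row, col, height, width) rectangles or shapely polygons.
    The whole-mask report comes first, named ``"whole"``.
    """
    reports = [score_report(class_distribution(mask), rules, policy, region="whole")]
    for i, region in enumerate(regions or []):
        dist = _region_distribution(mask, region)
        reports.append(score_report(dist, rules, policy, region=f"region_{i}"))
    return reports
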