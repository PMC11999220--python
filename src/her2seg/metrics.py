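"""Segmentation and slide-scoring evaluation metrics.

Three segmentation metrics are provided: the mean F1 score over the five
tissue classes (the four HER2 grades plus non-invasive; background is
excluded), a linearly weighted Cohen's kappa over the HER2 grades, and the
Concordance F1, which counts a predicted pixel as correct whenever it
matches at least one individual annotator rather than only the consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .consensus import MaskStack, hierarchical_consensus
from .core import INVASIVE_CLASSES, LabelMask, N_CLASSES, SchemaError, _GRADE

__all__ = [
    "UndefinedMetricError",
    "EvalReport",
    "confusion_matrix",
    "per_class_f1",
    "mean_f1",
    "weighted_kappa",
    "concordance_f1",
    "evaluate",
    "score_metrics",
    "status_metrics",
]

TISSUE_CLASS_IDS = (1, 2, 3, 4, 5)  # HER2 grades 0..3+ plus non-invasive


class UndefinedMetricError(ValueError):
    """The metric's domain is empty for these inputs."""


def _check_shapes(pred: LabelMask, ref: LabelMask) -> None:
    if pred.shape != ref.shape:
        raise SchemaError(f"shape mismatch: pred {pred.shape} vs ref {ref.shape}")


def confusion_matrix(pred: LabelMask, ref: LabelMask) -> np.ndarray:
    """6x6 count matrix indexed [reference, prediction]."""
    _check_shapes(pred, ref)
    idx = ref.data.ravel().astype(np.int64) * N_CLASSES + pred.data.ravel()
    return np.bincount(idx, minlength=N_CLASSES * N_CLASSES).reshape(N_CLASSES, N_CLASSES)


def per_class_f1(pred: LabelMask, ref: LabelMask) -> dict[int, float]:
    """F1 per class; classes absent from both masks map to NaN."""
    cm = confusion_matrix(pred, ref)
    out: dict[int, float] = {}
    for c in range(N_CLASSES):
        tp = cm[c, c]
        fp = cm[:, c].sum() - tp
        fn = cm[c, :].sum() - tp
        out[c] = float("nan") if tp + fp + fn == 0 else 2 * tp / (2 * tp + fp + fn)
    return out


def mean_f1(
    pred: LabelMask, ref: LabelMask, classes: tuple[int, ...] = TISSUE_CLASS_IDS
) -> tuple[float, dict[int, float]]:
    """Mean of per-class F1 over the five tissue classes.

    Classes absent from both prediction and reference are excluded from
    the mean rather than scored perfect, so small-ROI evaluations are not
    inflated.  Returns (mean, per-class dict).
    """
    f1 = per_class_f1(pred, ref)
    present = [f1[c] for c in classes if not np.isnan(f1[c])]
    if not present:
        raise UndefinedMetricError("no evaluated class present in either mask")
    return float(np.mean(present)), {c: f1[c] for c in classes}


def _linear_weighted_kappa_from_table(table: np.ndarray) -> float:
    n_levels = table.shape[0]
    n = table.sum()
    if n == 0:
        raise UndefinedMetricError("empty contingency table")
    i, j = np.indices((n_levels, n_levels))
    w = 1.0 - np.abs(i - j) / (n_levels - 1)
    obs = table / n
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / (n * n)
    po = float((w * obs).sum())
    pe = float((w * expected).sum())
    if pe == 1.0:
        return 1.0  # degenerate marginals: agreement can only be perfect
    return (po - pe) / (1.0 - pe)


def weighted_kappa(pred: LabelMask, ref: LabelMask) -> float:
    """Linearly weighted Cohen's kappa over the HER2 grades 0-3.

    Restricted to pixels where *both* masks carry an invasive class, so
    background and non-invasive changes do not move the statistic.
    Raises :class:`UndefinedMetricError` when no pixel is jointly invasive.
    """
    _check_shapes(pred, ref)
    both = np.isin(pred.data, INVASIVE_CLASSES) & np.isin(ref.data, INVASIVE_CLASSES)
    if not both.any():
        raise UndefinedMetricError("no jointly invasive pixels; kappa undefined")
    gp = _GRADE[pred.data[both]]
    gr = _GRADE[ref.data[both]]
    table = np.bincount(gr * 4 + gp, minlength=16).reshape(4, 4).astype(np.float64)
    return _linear_weighted_kappa_from_table(table)


def concordance_f1(
    pred: LabelMask, stack: MaskStack, consensus: LabelMask | None = None
) -> float:
    """Mean F1 against an oracle reference built from the annotator stack.

    Per pixel the oracle adopts the prediction when it matches at least one
    annotator's label there, and falls back to the consensus otherwise —
    so plausible minority opinions are not penalized.
    """
    if consensus is None:
        consensus = hierarchical_consensus(stack)
    _check_shapes(pred, consensus)
    arr = stack.as_array()
    matches_any = (arr == pred.data[None]).any(axis=0)
    ref_star = np.where(matches_any, pred.data, consensus.data).astype(np.uint8)
    oracle = LabelMask(ref_star, pred.spacing_um, pred.origin)
    return mean_f1(pred, oracle)[0]


@dataclass
class EvalReport:
    """Bundle of segmentation metrics for one prediction/reference pair."""

    per_class_f1: dict[int, float]
    mean_f1: float
    kappa: float | None
    concordance_f1: float | None
    confusion: np.ndarray

    @property
    def confusion_normalized(self) -> np.ndarray:
        rows = self.confusion.sum(axis=1, keepdims=True).astype(np.float64)
        with np.errstate(invalid="ignore"):
            out = self.confusion / rows
        return np.where(rows > 0, out, 0.0)

    def to_dict(self) -> dict:
        return {
            "mean_f1": self.mean_f1,
            "per_class_f1": {int(k): (None if np.isnan(v) else float(v)) for k, v in self.per_class_f1.items()},
            "kappa": self.kappa,
            "concordance_f1": self.concordance_f1,
            "confusion": self.confusion.tolist(),
        }


def evaluate(
    pred: LabelMask, ref: LabelMask, stack: MaskStack | None = None
) -> EvalReport:
    """Full evaluation of a prediction against a (consensus) reference."""
    mf1, pc = mean_f1(pred, ref)
    try:
        kappa = weighted_kappa(pred, ref)
    except UndefinedMetricError:
        kappa = None
    cf1 = concordance_f1(pred, stack, ref) if stack is not None else None
    return EvalReport(pc, mf1, kappa, cf1, confusion_matrix(pred, ref))


# ---------------------------------------------------------------------------
# case-level (whole-slide) scoring metrics


def score_metrics(pred_scores, ref_scores) -> dict[str, float]:
    """Accuracy, mean F1 over the four score classes, and linearly
    weighted kappa for case-level HER2 scores (values in {0,1,2,3}).

    All values returned as fractions in [0, 1] (kappa in [-1, 1]).
    """
    pred = np.asarray(pred_scores, dtype=np.int64)
    ref = np.asarray(ref_scores, dtype=np.int64)
    if pred.size == 0 or pred.shape != ref.shape:
        raise SchemaError("score lists must be non-empty and equal length")
    if pred.min() < 0 or pred.max() > 3 or ref.min() < 0 or ref.max() > 3:
        raise SchemaError("scores must lie in 0..3")
    table = np.bincount(ref * 4 + pred, minlength=16).reshape(4, 4).astype(np.float64)
    f1s = []
    for c in range(4):
        tp = table[c, c]
        fp = table[:, c].sum() - tp
        fn = table[c, :].sum() - tp
        if tp + fp + fn > 0:
            f1s.append(2 * tp / (2 * tp + fp + fn))
    return {
        "accuracy": float((pred == ref).mean()),
        "correct": int((pred == ref).sum()),
        "n": int(pred.size),
        "mean_f1": float(np.mean(f1s)),
        "kappa": _linear_weighted_kappa_from_table(table),
    }


def status_metrics(pred_scores, ref_scores, fish=None) -> dict:
    """HER2-status level accounting for a scored cohort.

    ``fish`` is an optional per-case iterable (True = amplified/positive,
    False = negative, None = not performed) resolving equivocal (2+) cases.
    Reports referral counts (predicted vs annotated 2+ cases), HER2-low
    accuracy (true low cases called 1+ directly or resolved through an
    equivocal prediction), and false-negative positives (FISH-positive
    cases predicted as 0/1+).
    """
    from .scoring import score_to_status

    pred = np.asarray(pred_scores, dtype=np.int64)
    ref = np.asarray(ref_scores, dtype=np.int64)
    if pred.shape != ref.shape or pred.size == 0:
        raise SchemaError("score lists must be non-empty and equal length")
    fish = [None] * pred.size if fish is None else list(fish)

    pred_status = [score_to_status(int(s), f) for s, f in zip(pred, fish)]
    ref_status = [score_to_status(int(s), f) for s, f in zip(ref, fish)]

    statuses = ("negative", "low", "equivocal", "positive")
    cm = {rs: {ps: 0 for ps in statuses} for rs in statuses}
    for rs, ps in zip(ref_status, pred_status):
        cm[rs][ps] += 1

    low_true = [i for i, rs in enumerate(ref_status) if rs == "low"]
    low_ok = sum(1 for i in low_true if pred[i] in (1, 2))
    fn_positive = sum(
        1 for i, rs in enumerate(ref_status) if rs == "positive" and pred[i] <= 1
    )
    return {
        "status_confusion": cm,
        "predicted_referrals": int((pred == 2).sum()),
        "annotated_referrals": int((ref == 2).sum()),
        "referrals_saved": int((ref == 2).sum() - (pred == 2).sum()),
        "her2_low_cases": len(low_true),
        "her2_low_accuracy": low_ok / len(low_true) if low_true else None,
        "false_negative_positives": fn_positive,
    }
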