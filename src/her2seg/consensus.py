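"""Multi-annotator mask fusion and inter-rater agreement.

Direct class-level majority voting can misrepresent tissue when, say,
three raters pick three different HER2 grades while two call the region
non-invasive.  The hierarchical consensus therefore first votes over the
three supercategories (background / invasive / non-invasive) and, when
invasive wins, takes the median HER2 grade over exactly the raters who
voted invasive.

Conventions (configurable): supercategory ties break with priority
invasive > noninvasive > background, since missing invasive tumor is the
clinically costlier error; half-grade medians round up, mirroring the
tendency to push borderline cases toward 2+ so follow-up testing happens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    BACKGROUND,
    LabelMask,
    N_CLASSES,
    NONINVASIVE,
    SchemaError,
    SUPERCATEGORY,
    _GRADE,
)

__all__ = ["MaskStack", "hierarchical_consensus", "pairwise_agreement"]

# supercategory codes used internally, in tie-break priority order
_SC_INVASIVE, _SC_NONINVASIVE, _SC_BACKGROUND = 0, 1, 2
_SC_OF_CLASS = np.array(
    [
        {"invasive": _SC_INVASIVE, "noninvasive": _SC_NONINVASIVE, "background": _SC_BACKGROUND}[
            SUPERCATEGORY[c]
        ]
        for c in range(N_CLASSES)
    ]
)


@dataclass
class MaskStack:
    """K >= 2 aligned label masks from different annotators."""

    masks: list[LabelMask]
    annotators: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.masks) < 2:
            raise SchemaError("a mask stack needs at least two annotators")
        shape = self.masks[0].shape
        spacing = self.masks[0].spacing_um
        for m in self.masks[1:]:
            if m.shape != shape:
                raise SchemaError(f"mask shapes differ: {m.shape} vs {shape}")
            if m.spacing_um != spacing:
                raise SchemaError("mask spacings differ within the stack")
        if self.annotators is None:
            self.annotators = [f"A{i + 1}" for i in range(len(self.masks))]
        if len(self.annotators) != len(self.masks):
            raise SchemaError("one annotator id per mask required")

    @property
    def k(self) -> int:
        return len(self.masks)

    def as_array(self) -> np.ndarray:
        """(K, H, W) label array."""
        return np.stack([m.data for m in self.masks])


def hierarchical_consensus(stack: MaskStack) -> LabelMask:
    """Fuse a stack of annotator masks into a consensus mask.

    Per pixel: plurality vote over supercategories (ties broken
    invasive > noninvasive > background); if invasive wins, the final class
    carries the median grade of the invasive voters, half-grades rounded up.
    """
    arr = stack.as_array()
    sc = _SC_OF_CLASS[arr]  # (K, H, W)
    votes = np.stack([(sc == code).sum(axis=0) for code in range(3)])  # (3, H, W)
    winner = np.argmax(votes, axis=0)  # first max = priority order

    out = np.full(arr.shape[1:], BACKGROUND, dtype=np.uint8)
    out[winner == _SC_NONINVASIVE] = NONINVASIVE

    inv_win = winner == _SC_INVASIVE
    if inv_win.any():
        grades = np.where(sc == _SC_INVASIVE, _GRADE[arr], np.nan).astype(np.float64)
        med = np.nanmedian(grades[:, inv_win], axis=0)
        out[inv_win] = np.ceil(med).astype(np.uint8) + 1  # grade g -> class g+1
    m0 = stack.masks[0]
    return LabelMask(out, m0.spacing_um, m0.origin)


def pairwise_agreement(
    stack: MaskStack, classes: tuple[int, ...] = (1, 2, 3, 4, 5)
) -> np.ndarray:
    """K x K matrix of mean F1 between every pair of annotators.

    The mean runs over ``classes`` (default: the five tissue classes);
    a class absent from both masks of a pair is excluded from that pair's
    mean.  The diagonal is 1 by definition.
    """
    from .metrics import mean_f1

    k = stack.k
    out = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            f1, _ = mean_f1(stack.masks[i], stack.masks[j], classes=classes)
            out[i, j] = out[j, i] = f1
    return out
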