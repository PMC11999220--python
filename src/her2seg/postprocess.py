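"""Connected-component promotion of non-invasive tissue regions.

Non-invasive (in situ) tumor typically forms a connected region whose
boundary is segmented correctly from local context even when its interior
is not.  Tissue components — connected components over the union of all
five non-background classes — containing at least one-third non-invasive
pixels are therefore relabelled entirely as non-invasive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label

from .core import BACKGROUND, LabelMask, NONINVASIVE, SchemaError

__all__ = ["PostprocessConfig", "tissue_components", "relabel_noninvasive"]


@dataclass
class PostprocessConfig:
    connectivity: int = 8  # pixel connectivity, 4 or 8
    noninvasive_fraction: float = 1.0 / 3.0  # inclusive threshold
    min_component_px: int = 1

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise SchemaError("connectivity must be 4 or 8")
        if not 0 < self.noninvasive_fraction <= 1:
            raise SchemaError("noninvasive_fraction must lie in (0, 1]")
        if self.min_component_px < 1:
            raise SchemaError("min_component_px must be >= 1")


def tissue_components(mask: LabelMask, cfg: PostprocessConfig | None = None) -> np.ndarray:
    """Label connected components of non-background tissue.

    Background is component 0; tissue component ids are contiguous from 1.
    """
    cfg = cfg or PostprocessConfig()
    mask.validate()
    skimage_conn = 1 if cfg.connectivity == 4 else 2
    return cc_label(mask.data != BACKGROUND, connectivity=skimage_conn)


def relabel_noninvasive(mask: LabelMask, cfg: PostprocessConfig | None = None) -> LabelMask:
    """Promote whole tissue components to NONINVASIVE.

    A component is promoted when its non-invasive pixel fraction is at
    least ``noninvasive_fraction`` (inclusive, default 1/3) and its size is
    at least ``min_component_px``.  All other pixels, including background,
    are untouched; the operation is idempotent.
    """
    cfg = cfg or PostprocessConfig()
    comps = tissue_components(mask, cfg)
    n = comps.max()
    if n == 0:
        return LabelMask(mask.data.copy(), mask.spacing_um, mask.origin)
    sizes = np.bincount(comps.ravel(), minlength=n + 1)
    ni = np.bincount(comps.ravel(), weights=(mask.data == NONINVASIVE).ravel(), minlength=n + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = ni / sizes
    promote = np.zeros(n + 1, dtype=bool)
    eligible = sizes >= cfg.min_component_px
    promote[1:] = eligible[1:] & (frac[1:] >= cfg.noninvasive_fraction)
    out = mask.data.copy()
    out[promote[comps]] = NONINVASIVE
    return LabelMask(out, mask.spacing_um, mask.origin)
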