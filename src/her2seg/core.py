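"""Label schema and raster containers shared by every pipeline stage.

The six-class tissue scheme covers the four invasive HER2 expression
grades (0, 1+, 2+, 3+), non-invasive (in situ) tumor tissue, and a single
aggregated background class.  Integer codes are a fixed on-disk contract:
masks serialize as plain 8-bit rasters with values 0-5.

Raster convention: 0-based (row, col) indexing, origin at the top-left,
half-open extents.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from PIL import Image

__all__ = [
    "BACKGROUND",
    "HER2_0",
    "HER2_1",
    "HER2_2",
    "HER2_3",
    "NONINVASIVE",
    "INVASIVE_CLASSES",
    "N_CLASSES",
    "TissueClass",
    "TISSUE_CLASSES",
    "CLASS_NAMES",
    "SUPERCATEGORY",
    "SchemaError",
    "LabelMask",
    "ProbabilityMap",
    "ClassDistribution",
    "grade_of",
    "class_for_grade",
    "class_distribution",
    "argmax_mask",
    "read_mask",
    "write_mask",
    "read_probability_map",
    "write_probability_map",
]

BACKGROUND = 0
HER2_0 = 1
HER2_1 = 2
HER2_2 = 3
HER2_3 = 4
NONINVASIVE = 5

#: The four invasive classes, in grade order 0, 1+, 2+, 3+.
INVASIVE_CLASSES = (HER2_0, HER2_1, HER2_2, HER2_3)
N_CLASSES = 6


class SchemaError(ValueError):
    """A raster or annotation violates the six-class label schema."""


@dataclass(frozen=True)
class TissueClass:
    """One entry of the label schema.

    ``her2_grade`` is the ordinal staining grade 0-3 and is defined exactly
    for the four invasive classes; ``supercategory`` is one of
    ``background``, ``invasive``, ``noninvasive``.
    """

    id: int
    name: str
    supercategory: str
    her2_grade: int | None = None

    def __post_init__(self) -> None:
        if (self.supercategory == "invasive") != (self.her2_grade is not None):
            raise SchemaError(
                f"class {self.name}: her2_grade defined iff supercategory is invasive"
            )


TISSUE_CLASSES: tuple[TissueClass, ...] = (
    TissueClass(BACKGROUND, "BACKGROUND", "background"),
    TissueClass(HER2_0, "HER2_0", "invasive", 0),
    TissueClass(HER2_1, "HER2_1", "invasive", 1),
    TissueClass(HER2_2, "HER2_2", "invasive", 2),
    TissueClass(HER2_3, "HER2_3", "invasive", 3),
    TissueClass(NONINVASIVE, "NONINVASIVE", "noninvasive"),
)

CLASS_NAMES = {c.name: c.id for c in TISSUE_CLASSES}
SUPERCATEGORY = {c.id: c.supercategory for c in TISSUE_CLASSES}

# grade lookup as an array: -1 marks non-invasive classes
_GRADE = np.full(N_CLASSES, -1, dtype=np.int64)
for _c in TISSUE_CLASSES:
    if _c.her2_grade is not None:
        _GRADE[_c.id] = _c.her2_grade


def grade_of(class_id: int) -> int | None:
    """HER2 grade (0-3) of an invasive class id, ``None`` otherwise."""
    g = _GRADE[class_id]
    return None if g < 0 else int(g)


def class_for_grade(grade: int) -> int:
    """Class id carrying the given HER2 grade."""
    if not 0 <= grade <= 3:
        raise SchemaError(f"HER2 grade must be in 0..3, got {grade}")
    return INVASIVE_CLASSES[grade]


@dataclass
class LabelMask:
    """2D class raster with a physical pixel spacing.

    Parameters
    ----------
    data
        2D integer array with values in ``{0..5}``.
    spacing_um
        Micrometres per pixel (the pipeline's working resolution is
        2.0 µm/px).
    origin
        (row, col) offset of this raster within slide coordinates.
    """

    data: np.ndarray
    spacing_um: float = 2.0
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.validate()

    def validate(self) -> None:
        if self.data.ndim != 2:
            raise SchemaError(f"label mask must be 2D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise SchemaError(f"label mask must be integer-typed, got {self.data.dtype}")
        if self.data.size:
            lo, hi = int(self.data.min()), int(self.data.max())
            if lo < 0 or hi >= N_CLASSES:
                bad = lo if lo < 0 else hi
                raise SchemaError(f"invalid class value {bad} in label mask")
        if not self.spacing_um > 0:
            raise SchemaError(f"spacing_um must be positive, got {self.spacing_um}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class ProbabilityMap:
    """Per-pixel distribution over the six tissue classes (H x W x 6)."""

    data: np.ndarray
    spacing_um: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.validate()

    def validate(self, atol: float = 1e-6) -> None:
        if self.data.ndim != 3 or self.data.shape[2] != N_CLASSES:
            raise SchemaError(
                f"probability map must be H x W x {N_CLASSES}, got {self.data.shape}"
            )
        if self.data.size:
            if self.data.min() < -atol or self.data.max() > 1 + atol:
                raise SchemaError("probabilities must lie in [0, 1]")
            sums = self.data.sum(axis=2)
            if not np.allclose(sums, 1.0, atol=atol):
                raise SchemaError("per-pixel class probabilities must sum to 1")
        if not self.spacing_um > 0:
            raise SchemaError(f"spacing_um must be positive, got {self.spacing_um}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]  # type: ignore[return-value]


@dataclass
class ClassDistribution:
    """Per-class pixel counts; the input to the slide-level scoring rules."""

    counts: Mapping[int, int]

    def __post_init__(self) -> None:
        counts = {int(k): int(v) for k, v in self.counts.items()}
        for k, v in counts.items():
            if not 0 <= k < N_CLASSES:
                raise SchemaError(f"invalid class id {k} in distribution")
            if v < 0:
                raise SchemaError(f"negative count {v} for class {k}")
        self.counts = counts

    @property
    def n_invasive(self) -> int:
        return sum(self.counts.get(c, 0) for c in INVASIVE_CLASSES)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def grade_counts(self) -> dict[int, int]:
        """Invasive pixel counts keyed by HER2 grade 0-3."""
        return {g: self.counts.get(class_for_grade(g), 0) for g in range(4)}


def class_distribution(mask: LabelMask) -> ClassDistribution:
    """Tally pixels per tissue class.

    Pixel proportions stand in for cell proportions throughout the scoring
    stage, so this tally is the sufficient statistic for a slide's score.
    """
    mask.validate()
    counts = np.bincount(mask.data.ravel(), minlength=N_CLASSES)
    return ClassDistribution({c: int(counts[c]) for c in range(N_CLASSES) if counts[c]})


def argmax_mask(probs: ProbabilityMap) -> LabelMask:
    """Collapse a probability map to the per-pixel most likely class.

    Ties are broken toward the lowest class id (deterministic contract).
    """
    probs.validate()
    data = np.argmax(probs.data, axis=2).astype(np.uint8)
    return LabelMask(data, spacing_um=probs.spacing_um)


# ---------------------------------------------------------------------------
# raster IO


def write_mask(mask: LabelMask, path: str | Path) -> None:
    """Write a label mask as a single-channel 8-bit PNG/TIFF."""
    Image.fromarray(mask.data.astype(np.uint8), mode="L").save(str(path))


def read_mask(path: str | Path, spacing_um: float = 2.0) -> LabelMask:
    """Read an 8-bit raster with values 0-5 as a :class:`LabelMask`."""
    arr = np.asarray(Image.open(str(path)).convert("L"), dtype=np.uint8)
    return LabelMask(arr, spacing_um=spacing_um)


def write_probability_map(pmap: ProbabilityMap, path: str | Path) -> None:
    """Write a probability map as multi-channel TIFF plus a JSON sidecar.

    The sidecar records pixel spacing and channel order so the container is
    self-describing.
    """
    import tifffile

    path = Path(path)
    tifffile.imwrite(str(path), pmap.data.astype(np.float32))
    sidecar = {
        "spacing_um": pmap.spacing_um,
        "channels": [c.name for c in TISSUE_CLASSES],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_probability_map(path: str | Path) -> ProbabilityMap:
    import tifffile

    path = Path(path)
    data = np.asarray(tifffile.imread(str(path)), dtype=np.float64)
    spacing = 2.0
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        spacing = float(meta.get("spacing_um", spacing))
    # renormalize float32 storage error before validation
    data = data / data.sum(axis=2, keepdims=True)
    return ProbabilityMap(data, spacing_um=spacing)
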