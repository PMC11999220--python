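"""Polygon annotation IO and rasterization.

Annotations travel as GeoJSON FeatureCollections of Polygon features with
``label`` and ``annotator`` properties, in pixel coordinates at the mask's
stated spacing.  Rasterization paints polygons in decreasing-area order so
that small, granular polygons (down to single cells) override the coarse
regions that contain them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely import contains_xy
from shapely.geometry import Polygon, shape
from shapely.validation import make_valid

from .core import BACKGROUND, CLASS_NAMES, LabelMask, N_CLASSES, SchemaError, TISSUE_CLASSES

__all__ = [
    "PolygonAnnotation",
    "AnnotationSet",
    "AnnotationError",
    "read_annotations",
    "write_annotations",
    "rasterize",
]


class AnnotationError(ValueError):
    """A feature could not be parsed into a valid polygon annotation."""


def _parse_label(value: object) -> int:
    if isinstance(value, bool):
        raise SchemaError(f"unknown label {value!r}")
    if isinstance(value, (int, np.integer)):
        if 0 <= int(value) < N_CLASSES:
            return int(value)
        raise SchemaError(f"unknown label id {value}")
    if isinstance(value, str):
        if value in CLASS_NAMES:
            return CLASS_NAMES[value]
        if value.isdigit() and int(value) < N_CLASSES:
            return int(value)
        raise SchemaError(f"unknown label name {value!r}")
    raise SchemaError(f"unknown label {value!r}")


@dataclass
class PolygonAnnotation:
    """A labelled polygon in pixel coordinates.

    Vertices are (x, y) = (col, row).  Geometry is cleaned on construction
    (self-intersections resolved via the largest valid polygon part).
    """

    vertices: list[tuple[float, float]]
    label: int
    annotator: str = ""
    roi: str | None = None
    id: int = 0

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise AnnotationError(
                f"polygon {self.id}: needs at least 3 vertices, got {len(self.vertices)}"
            )
        if not 0 <= self.label < N_CLASSES:
            raise SchemaError(f"polygon {self.id}: unknown label id {self.label}")
        geom = Polygon(self.vertices)
        if not geom.is_valid:
            cleaned = make_valid(geom)
            polys = [g for g in getattr(cleaned, "geoms", [cleaned]) if isinstance(g, Polygon)]
            if not polys:
                raise AnnotationError(f"polygon {self.id}: degenerate geometry")
            geom = max(polys, key=lambda g: g.area)
        if geom.area == 0:
            raise AnnotationError(f"polygon {self.id}: zero-area geometry")
        self.geometry: Polygon = geom

    @property
    def area_px(self) -> float:
        return self.geometry.area


@dataclass
class AnnotationSet:
    """Container for one canvas' polygon annotations."""

    polygons: list[PolygonAnnotation]
    canvas: tuple[int, int]  # (height, width)
    spacing_um: float = 2.0

    def __post_init__(self) -> None:
        if len(self.canvas) != 2 or min(self.canvas) <= 0:
            raise SchemaError(f"invalid canvas {self.canvas}")

    def annotators(self) -> list[str]:
        return sorted({p.annotator for p in self.polygons})


def read_annotations(
    path: str | Path, canvas: tuple[int, int] | None = None, spacing_um: float = 2.0
) -> AnnotationSet:
    """Parse a GeoJSON FeatureCollection of labelled polygons.

    Malformed geometry or an unknown label raises, naming the feature index.
    The canvas may be given in a top-level ``canvas`` member ([height,
    width]) or via the ``canvas`` argument.
    """
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise AnnotationError("expected a GeoJSON FeatureCollection")
    polygons: list[PolygonAnnotation] = []
    for i, feat in enumerate(doc.get("features", [])):
        try:
            geom = shape(feat["geometry"])
            if not isinstance(geom, Polygon):
                raise AnnotationError(f"geometry type {geom.geom_type} is not Polygon")
            props = feat.get("properties", {}) or {}
            label = _parse_label(props.get("label"))
            polygons.append(
                PolygonAnnotation(
                    vertices=[(float(x), float(y)) for x, y in geom.exterior.coords[:-1]],
                    label=label,
                    annotator=str(props.get("annotator", "")),
                    roi=props.get("roi"),
                    id=i,
                )
            )
        except SchemaError:
            raise
        except (AnnotationError, KeyError, TypeError, ValueError) as exc:
            raise AnnotationError(f"feature {i}: {exc}") from exc
    if canvas is None:
        if "canvas" not in doc:
            raise AnnotationError("no canvas size in file; pass canvas=(H, W)")
        canvas = tuple(int(v) for v in doc["canvas"])  # type: ignore[assignment]
    spacing_um = float(doc.get("spacing_um", spacing_um))
    return AnnotationSet(polygons, canvas, spacing_um)


def write_annotations(aset: AnnotationSet, path: str | Path) -> None:
    features = []
    for p in aset.polygons:
        ring = [[float(x), float(y)] for x, y in p.vertices]
        ring.append(ring[0])
        props: dict = {"label": TISSUE_CLASSES[p.label].name, "annotator": p.annotator}
        if p.roi is not None:
            props["roi"] = p.roi
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": props,
            }
        )
    doc = {
        "type": "FeatureCollection",
        "canvas": list(aset.canvas),
        "spacing_um": aset.spacing_um,
        "features": features,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def rasterize(aset: AnnotationSet, scale: float = 1.0) -> LabelMask:
    """Convert polygon annotations to a pixel-wise label mask.

    Unannotated pixels become BACKGROUND.  Polygons are painted in
    decreasing-area order (ties broken by annotation id) so that smaller,
    more granular polygons override larger ones.  A pixel belongs to a
    polygon when its center (col + 0.5, row + 0.5) lies inside the cleaned
    geometry.  ``scale`` multiplies annotation coordinates before painting,
    e.g. 0.25 maps 0.5 µm/px annotations onto a 2.0 µm/px mask.
    """
    h, w = aset.canvas
    out = np.full((h, w), BACKGROUND, dtype=np.uint8)
    order = sorted(aset.polygons, key=lambda p: (-p.area_px * scale * scale, p.id))
    for poly in order:
        geom = poly.geometry
        if scale != 1.0:
            import shapely.affinity as _aff

            geom = _aff.scale(geom, xfact=scale, yfact=scale, origin=(0, 0))
        minx, miny, maxx, maxy = geom.bounds
        c0, c1 = max(0, int(np.floor(minx - 0.5))), min(w - 1, int(np.ceil(maxx)))
        r0, r1 = max(0, int(np.floor(miny - 0.5))), min(h - 1, int(np.ceil(maxy)))
        if c1 < c0 or r1 < r0:
            warnings.warn(f"polygon {poly.id} lies outside the canvas; skipped")
            continue
        cols = np.arange(c0, c1 + 1) + 0.5
        rows = np.arange(r0, r1 + 1) + 0.5
        cc, rr = np.meshgrid(cols, rows)
        inside = contains_xy(geom, cc.ravel(), rr.ravel()).reshape(cc.shape)
        if not inside.any():
            warnings.warn(f"polygon {poly.id} covers no pixel centers; skipped")
            continue
        block = out[r0 : r1 + 1, c0 : c1 + 1]
        block[inside] = poly.label
    return LabelMask(out, spacing_um=aset.spacing_um)
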