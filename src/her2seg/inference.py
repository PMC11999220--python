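"""Tiled whole-slide inference with Gaussian-weighted patch fusion.

A large RGB image is reflection-padded, tiled at 50% overlap with
512-pixel patches (the working configuration at 2.0 µm/px), and each tile
is pushed through an arbitrary per-patch segmenter.  Patch probabilities
are fused by a Gaussian window centred on each tile, which removes seam
artefacts.  Near-white patches are detected by a 5th-percentile intensity
rule (threshold 250 on white-background uint8 images) and skipped: a
skipped tile contributes an explicit one-hot background distribution with
the same window weights, so even a fully white slide yields a defined map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np

from .core import BACKGROUND, N_CLASSES, ProbabilityMap, SchemaError

__all__ = [
    "InferenceConfig",
    "Segmenter",
    "gaussian_window",
    "is_foreground_patch",
    "sliding_window_predict",
    "heuristic_segment",
    "null_segment",
    "resample_to_spacing",
]


@dataclass
class InferenceConfig:
    """Tiling and foreground-detection parameters.

    ``sigma_scale`` expresses the Gaussian window's σ as a fraction of the
    patch size (default 1/8, i.e. σ = 64 px for 512-px patches).
    """

    patch_size: int = 512
    overlap_fraction: float = 0.5
    sigma_scale: float = 1.0 / 8.0
    target_spacing_um: float = 2.0
    fg_percentile: float = 5.0
    fg_intensity_threshold: int = 250
    skip_background: bool = True

    def __post_init__(self) -> None:
        if self.patch_size <= 0:
            raise SchemaError("patch_size must be positive")
        if not 0 < self.overlap_fraction < 1:
            raise SchemaError("overlap_fraction must lie in (0, 1)")
        if not 0 <= self.fg_intensity_threshold <= 255:
            raise SchemaError("fg_intensity_threshold must lie in [0, 255]")

    @property
    def stride(self) -> int:
        return max(1, round(self.patch_size * (1.0 - self.overlap_fraction)))


class Segmenter(Protocol):
    """Backend contract: RGB uint8 patch -> H x W x 6 probability raster."""

    def __call__(self, patch: np.ndarray) -> np.ndarray: ...


def gaussian_window(patch_size: int, sigma_scale: float = 1.0 / 8.0) -> np.ndarray:
    """Separable isotropic Gaussian weight map with peak 1.0 at the center.

    Strictly positive everywhere (floored at 1e-8) so every covered pixel
    receives weight.
    """
    if patch_size < 1:
        raise SchemaError("patch_size must be >= 1")
    sigma = sigma_scale * patch_size
    x = np.arange(patch_size) - (patch_size - 1) / 2.0
    g1 = np.exp(-(x**2) / (2.0 * sigma**2)) if sigma > 0 else (x == 0).astype(float)
    w = np.outer(g1, g1)
    w /= w.max()
    return np.maximum(w, 1e-8)


def is_foreground_patch(patch: np.ndarray, cfg: InferenceConfig | None = None) -> bool:
    """True when the patch contains enough non-white material to segment.

    The per-pixel minimum channel is used as the intensity: the patch is
    foreground iff its ``fg_percentile``-th percentile intensity falls
    below ``fg_intensity_threshold``.
    """
    cfg = cfg or InferenceConfig()
    patch = np.asarray(patch)
    intensity = patch.min(axis=2) if patch.ndim == 3 else patch
    return bool(np.percentile(intensity, cfg.fg_percentile) < cfg.fg_intensity_threshold)


def _reflect_pad(image: np.ndarray, pad_b: int, pad_r: int) -> np.ndarray:
    """Half-sample symmetric reflection padding on the bottom/right edges.

    Symmetric reflection stays defined for pads up to the image size; pads
    beyond that (tiny images) are applied in repeated passes.
    """
    out = image
    while pad_b > 0 or pad_r > 0:
        db = min(pad_b, out.shape[0])
        dr = min(pad_r, out.shape[1])
        spec = [(0, db), (0, dr)] + [(0, 0)] * (out.ndim - 2)
        out = np.pad(out, spec, mode="symmetric")
        pad_b -= db
        pad_r -= dr
    return out


def sliding_window_predict(
    image: np.ndarray,
    segmenter: Callable[[np.ndarray], np.ndarray],
    cfg: InferenceConfig | None = None,
) -> ProbabilityMap:
    """Run a per-patch segmenter over a large image and fuse the tiles.

    The image must already be at the target spacing (see
    :func:`resample_to_spacing`).  The fused map at every pixel is the
    Gaussian-weighted mean of all tile predictions covering it, cropped to
    the original extent and renormalized per pixel.
    """
    cfg = cfg or InferenceConfig()
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise SchemaError(f"expected an H x W x 3 RGB image, got {image.shape}")
    if image.size == 0:
        raise SchemaError("image is empty")
    h, w = image.shape[:2]
    ps, stride = cfg.patch_size, cfg.stride

    def n_tiles(extent: int) -> int:
        if extent <= ps:
            return 1
        return int(np.ceil((extent - ps) / stride)) + 1

    nr, nc = n_tiles(h), n_tiles(w)
    hp = ps + (nr - 1) * stride
    wp = ps + (nc - 1) * stride
    padded = _reflect_pad(image, hp - h, wp - w)

    window = gaussian_window(ps, cfg.sigma_scale)
    num = np.zeros((hp, wp, N_CLASSES), dtype=np.float64)
    den = np.zeros((hp, wp), dtype=np.float64)
    bg_onehot = None
    for ti in range(nr):
        for tj in range(nc):
            r0, c0 = ti * stride, tj * stride
            patch = padded[r0 : r0 + ps, c0 : c0 + ps]
            if cfg.skip_background and not is_foreground_patch(patch, cfg):
                if bg_onehot is None:
                    bg_onehot = np.zeros((ps, ps, N_CLASSES))
                    bg_onehot[..., BACKGROUND] = 1.0
                probs = bg_onehot
            else:
                probs = np.asarray(segmenter(patch), dtype=np.float64)
                if probs.shape != (ps, ps, N_CLASSES):
                    raise SchemaError(
                        f"segmenter returned shape {probs.shape}, "
                        f"expected {(ps, ps, N_CLASSES)}"
                    )
            num[r0 : r0 + ps, c0 : c0 + ps] += window[..., None] * probs
            den[r0 : r0 + ps, c0 : c0 + ps] += window
    fused = num[:h, :w] / den[:h, :w, None]
    fused /= fused.sum(axis=2, keepdims=True)
    return ProbabilityMap(fused, spacing_um=cfg.target_spacing_um)


def resample_to_spacing(
    image: np.ndarray, spacing_um: float, target_spacing_um: float = 2.0
) -> np.ndarray:
    """Area-average an RGB image from its native spacing to the working
    resolution (antialiased downsampling of stain intensity)."""
    from skimage.transform import resize

    factor = spacing_um / target_spacing_um
    h = max(1, round(image.shape[0] * factor))
    w = max(1, round(image.shape[1] * factor))
    out = resize(image.astype(np.float64), (h, w), anti_aliasing=True, mode="reflect")
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# demo backends

# Color contract shared with her2seg.synthetic.render_pseudo_ihc: background
# is near-white (all channels >= 252), invasive tissue is brown (red clearly
# above blue) with the blue channel encoding staining density in four bands,
# and non-invasive tissue carries a blue-violet hue marker (blue above red).
WHITE_MIN = 248
NONINVASIVE_HUE_MARGIN = 15
GRADE_BLUE_EDGES = (58, 105, 150)  # B < 58 -> 3+, < 105 -> 2+, < 150 -> 1+, else 0


def heuristic_segment(patch: np.ndarray) -> np.ndarray:
    """Rule-based demo segmenter for pseudo-IHC renders.

    Classifies by color alone: near-white pixels are background, blue-over-
    red pixels are non-invasive, and brown pixels are binned into the four
    HER2 grades by blue-channel optical density.  Output is one-hot.
    """
    patch = np.asarray(patch, dtype=np.int16)
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise SchemaError(f"expected an RGB patch, got shape {patch.shape}")
    r, b = patch[..., 0], patch[..., 2]
    labels = np.empty(patch.shape[:2], dtype=np.int64)
    # grade by blue-channel band, darkest = strongest staining
    labels[:] = 4  # HER2_3
    for cls, edge in zip((3, 2, 1), GRADE_BLUE_EDGES):
        labels[b >= edge] = cls
    labels[b >= r + NONINVASIVE_HUE_MARGIN] = 5  # NONINVASIVE hue marker
    labels[patch.min(axis=2) >= WHITE_MIN] = BACKGROUND
    out = np.zeros((*patch.shape[:2], N_CLASSES), dtype=np.float64)
    np.put_along_axis(out, labels[..., None], 1.0, axis=2)
    return out


def null_segment(patch: np.ndarray) -> np.ndarray:
    """Backend that declares everything background (pipeline dry runs)."""
    out = np.zeros((*np.asarray(patch).shape[:2], N_CLASSES), dtype=np.float64)
    out[..., BACKGROUND] = 1.0
    return out
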