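"""End-to-end pipeline: image / probability map / mask -> HER2 score report.

Exactly one input stage is supplied; later stages are inferred.  An RGB
image is segmented by the configured backend through the sliding-window
engine, the probability map is collapsed by argmax, the label mask is
post-processed (non-invasive component promotion) and finally scored.
The run is a pure function of inputs and configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Callable

import numpy as np

from .core import LabelMask, ProbabilityMap, SchemaError, argmax_mask, class_distribution
from .inference import InferenceConfig, heuristic_segment, null_segment, sliding_window_predict
from .postprocess import PostprocessConfig, relabel_noninvasive
from .scoring import MarginPolicy, ScoringRules, score_report

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "BACKENDS"]

BACKENDS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "heuristic": heuristic_segment,
    "null": null_segment,
}


@dataclass
class PipelineConfig:
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    rules: ScoringRules = field(default_factory=ScoringRules)
    margin: MarginPolicy = field(default_factory=MarginPolicy)
    backend: str = "heuristic"
    fish: bool | None = None
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    report: dict
    mask: LabelMask
    probs: ProbabilityMap | None
    config_hash: str

    def to_json(self) -> str:
        return json.dumps(
            {"config_hash": self.config_hash, **self.report}, indent=2, sort_keys=True
        )


def run_pipeline(
    image: np.ndarray | None = None,
    probs: ProbabilityMap | None = None,
    mask: LabelMask | None = None,
    cfg: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the pipeline from whichever stage an input is supplied for."""
    cfg = cfg or PipelineConfig()
    supplied = sum(x is not None for x in (image, probs, mask))
    if supplied != 1:
        raise SchemaError("supply exactly one of image, probs, mask")
    if image is not None:
        segmenter = BACKENDS.get(cfg.backend)
        if segmenter is None:
            raise SchemaError(
                f"unknown backend {cfg.backend!r}; available: {sorted(BACKENDS)}"
            )
        probs = sliding_window_predict(image, segmenter, cfg.inference)
    if probs is not None:
        mask = argmax_mask(probs)
    assert mask is not None
    mask = relabel_noninvasive(mask, cfg.postprocess)
    report = score_report(
        class_distribution(mask), cfg.rules, cfg.margin, fish=cfg.fish
    ).to_dict()
    return PipelineResult(report, mask, probs, cfg.config_hash())
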