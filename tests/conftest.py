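import numpy as np
import pytest

from her2seg.core import ClassDistribution, LabelMask, N_CLASSES, ProbabilityMap


def mask_from_counts(counts: dict[int, int], width: int = 10) -> LabelMask:
    """Flat mask realizing exact per-class pixel counts (row-major fill)."""
    values = np.concatenate([np.full(n, c, dtype=np.uint8) for c, n in counts.items()])
    total = values.size
    height = -(-total // width)
    padded = np.concatenate([values, np.zeros(height * width - total, dtype=np.uint8)])
    return LabelMask(padded.reshape(height, width))


def dist_from_counts(counts: dict[int, int]) -> ClassDistribution:
    return ClassDistribution(counts)


def random_mask(rng: np.random.Generator, shape=(16, 16)) -> LabelMask:
    return LabelMask(rng.integers(0, N_CLASSES, size=shape).astype(np.uint8))


def random_probs(rng: np.random.Generator, shape=(16, 16)) -> ProbabilityMap:
    raw = rng.random((*shape, N_CLASSES)) + 1e-3
    return ProbabilityMap(raw / raw.sum(axis=2, keepdims=True))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
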