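"""Ground metric and Wasserstein Dice loss, against brute-force oracles."""

import numpy as np
import pytest

from her2seg.core import (
    BACKGROUND,
    HER2_0,
    HER2_1,
    HER2_2,
    HER2_3,
    LabelMask,
    N_CLASSES,
    NONINVASIVE,
    ProbabilityMap,
    SchemaError,
)
from her2seg.wdice import (
    EPS_EMPTY_FG,
    GroundMetric,
    LossConfig,
    build_her2_ground_metric,
    combined_loss,
    cross_entropy_loss,
    pixel_transport_cost,
    wasserstein_dice_grad,
    wasserstein_dice_loss,
)
from conftest import random_mask, random_probs


def brute_force_wdl(probs, truth, metric, clamp=True, bg=0):
    """Independent double-loop implementation of the loss."""
    h, w = truth.data.shape
    e = 0.0
    tp = 0.0
    any_fg = False
    for i in range(h):
        for j in range(w):
            g = int(truth.data[i, j])
            wx = sum(metric.m[g, l] * probs.data[i, j, l] for l in range(N_CLASSES))
            e += wx
            if g != bg:
                any_fg = True
                term = metric.m[g, bg] - wx
                tp += max(term, 0.0) if clamp else term
    if not any_fg:
        return e / (e + EPS_EMPTY_FG)
    return 1.0 - 2 * tp / (2 * tp + e) if (2 * tp + e) else 0.0


def one_hot(mask: LabelMask) -> ProbabilityMap:
    out = np.zeros((*mask.shape, N_CLASSES))
    np.put_along_axis(out, mask.data[..., None].astype(np.int64), 1.0, axis=2)
    return ProbabilityMap(out)


class TestGroundMetric:
    def test_her2_penalties(self):
        m = build_her2_ground_metric().m
        assert m[HER2_0, HER2_1] == 0.25
        assert m[HER2_0, HER2_2] == 0.50
        assert m[HER2_0, HER2_3] == 1.00
        assert m[HER2_1, HER2_2] == 0.25
        assert m[HER2_2, HER2_2] == 0.0

    def test_noninvasive_and_background_penalties(self):
        m = build_her2_ground_metric().m
        for c in (HER2_0, HER2_1, HER2_2, HER2_3):
            assert m[c, NONINVASIVE] == 0.50
            assert m[BACKGROUND, c] == 1.00
        assert m[BACKGROUND, NONINVASIVE] == 1.00

    def test_symmetric_zero_diagonal(self):
        metric = build_her2_ground_metric()
        assert np.allclose(metric.m, metric.m.T)
        assert np.all(np.diag(metric.m) == 0)

    def test_rejects_asymmetric(self):
        m = build_her2_ground_metric().m.copy()
        m[0, 1] = 0.7
        with pytest.raises(SchemaError, match="symmetric"):
            GroundMetric(m)


class TestPixelTransportCost:
    metric = build_her2_ground_metric()

    def test_correct_one_hot_is_free(self):
        p = np.zeros(6)
        p[HER2_1] = 1.0
        assert pixel_transport_cost(p, HER2_1, self.metric) == 0.0

    def test_neighbor_grade_costs_quarter(self):
        p = np.zeros(6)
        p[HER2_2] = 1.0
        assert pixel_transport_cost(p, HER2_1, self.metric) == 0.25

    def test_half_background_half_correct(self):
        p = np.zeros(6)
        p[BACKGROUND] = 0.5
        p[HER2_1] = 0.5
        assert pixel_transport_cost(p, HER2_1, self.metric) == pytest.approx(0.5)

    def test_unnormalized_rejected(self):
        with pytest.raises(SchemaError):
            pixel_transport_cost(np.full(6, 0.3), HER2_1, self.metric)


class TestWassersteinDiceLoss:
    metric = build_her2_ground_metric()

    def test_perfect_prediction_is_zero(self, rng):
        truth = random_mask(rng, (8, 8))
        if not (truth.data != 0).any():
            truth.data[0, 0] = HER2_2
        assert wasserstein_dice_loss(one_hot(truth), truth, self.metric) == 0.0

    def test_single_pixel_worst_case(self):
        truth = LabelMask(np.array([[HER2_3]], dtype=np.uint8))
        pred = one_hot(LabelMask(np.array([[BACKGROUND]], dtype=np.uint8)))
        assert wasserstein_dice_loss(pred, truth, self.metric) == pytest.approx(1.0)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(25):
            truth = random_mask(rng, (8, 8))
            probs = random_probs(rng, (8, 8))
            got = wasserstein_dice_loss(probs, truth, self.metric)
            want = brute_force_wdl(probs, truth, self.metric)
            assert got == pytest.approx(want, abs=1e-10)

    def test_zero_one_metric_reduces_to_foreground_dice(self, rng):
        metric01 = GroundMetric(1.0 - np.eye(6))
        for _ in range(10):
            truth = random_mask(rng, (6, 6))
            if not (truth.data != 0).any():
                truth.data[0, 0] = HER2_1
            probs = random_probs(rng, (6, 6))
            rows, cols = np.indices(truth.shape)
            p_true = probs.data[rows, cols, truth.data]
            c = p_true[truth.data != 0].sum()  # correct mass on foreground
            e = (1.0 - p_true).sum()  # misclassified mass everywhere
            want = 1.0 - 2 * c / (2 * c + e)
            assert wasserstein_dice_loss(probs, truth, metric01) == pytest.approx(want, abs=1e-10)

    def test_severity_ordering(self, rng):
        for _ in range(20):
            truth = LabelMask(
                rng.choice([BACKGROUND, HER2_1], size=(10, 10), p=[0.4, 0.6]).astype(np.uint8)
            )
            losses = []
            for wrong in (HER2_2, HER2_3, BACKGROUND):
                pred = truth.data.copy()
                pred[truth.data == HER2_1] = wrong
                losses.append(
                    wasserstein_dice_loss(one_hot(LabelMask(pred)), truth, self.metric)
                )
            assert losses[0] < losses[1] < losses[2]

    def test_joint_pixel_permutation_invariance(self, rng):
        truth = random_mask(rng, (6, 6))
        probs = random_probs(rng, (6, 6))
        perm = rng.permutation(36)
        truth_p = LabelMask(truth.data.ravel()[perm].reshape(6, 6))
        probs_p = ProbabilityMap(probs.data.reshape(36, 6)[perm].reshape(6, 6, 6))
        assert wasserstein_dice_loss(probs, truth, self.metric) == pytest.approx(
            wasserstein_dice_loss(probs_p, truth_p, self.metric), abs=1e-12
        )

    def test_all_background_truth_degenerate(self, rng):
        truth = LabelMask(np.zeros((4, 4), dtype=np.uint8))
        probs = random_probs(rng, (4, 4))
        loss = wasserstein_dice_loss(probs, truth, self.metric)
        assert 0 < loss < 1
        assert wasserstein_dice_loss(one_hot(truth), truth, self.metric) == 0.0

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(SchemaError, match="mismatch"):
            wasserstein_dice_loss(random_probs(rng, (4, 4)), random_mask(rng, (5, 5)))

    def test_analytic_gradient_matches_central_differences(self, rng):
        truth = random_mask(rng, (4, 4))
        truth.data[0, 0] = HER2_1  # ensure foreground
        raw = rng.random((4, 4, 6)) + 0.1
        # gradient w.r.t. the probability tensor itself (no renormalization)
        p0 = raw / raw.sum(axis=2, keepdims=True)
        grad = wasserstein_dice_grad(ProbabilityMap(p0), truth, self.metric)
        eps = 1e-6
        for idx in [(0, 0, 1), (1, 2, 0), (3, 3, 5), (2, 1, 3)]:
            dp = np.zeros_like(p0)
            dp[idx] = eps
            num = (_loss_p(p0 + dp, truth, self.metric) - _loss_p(p0 - dp, truth, self.metric)) / (
                2 * eps
            )
            assert num == pytest.approx(grad[idx], abs=1e-4)


def _loss_p(p, truth, metric):
    # bypass normalization validation for finite-difference probing
    pm = ProbabilityMap.__new__(ProbabilityMap)
    pm.data = p
    pm.spacing_um = 2.0
    return wasserstein_dice_loss(pm, truth, metric)


class TestCombinedLoss:
    metric = build_her2_ground_metric()

    def test_perfect_prediction_near_zero(self, rng):
        truth = random_mask(rng, (6, 6))
        truth.data[0, 0] = HER2_1
        assert combined_loss(one_hot(truth), truth, self.metric) == pytest.approx(0.0, abs=1e-9)

    def test_zero_wdl_weight_reduces_to_cross_entropy(self, rng):
        truth, probs = random_mask(rng, (6, 6)), random_probs(rng, (6, 6))
        cfg = LossConfig(ce_weight=1.0, wdl_weight=0.0)
        assert combined_loss(probs, truth, self.metric, cfg) == pytest.approx(
            cross_entropy_loss(probs, truth)
        )

    def test_sum_of_independent_terms(self, rng):
        truth, probs = random_mask(rng, (4, 4)), random_probs(rng, (4, 4))
        cfg = LossConfig(ce_weight=0.7, wdl_weight=1.3)
        want = 0.7 * cross_entropy_loss(probs, truth) + 1.3 * wasserstein_dice_loss(
            probs, truth, self.metric
        )
        assert combined_loss(probs, truth, self.metric, cfg) == pytest.approx(want, abs=1e-12)

    def test_both_weights_zero_rejected(self):
        with pytest.raises(SchemaError):
            LossConfig(ce_weight=0.0, wdl_weight=0.0)
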